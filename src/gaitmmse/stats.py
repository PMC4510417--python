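"""Group-level statistics on MMSE curves.

Per analysis scheme, a two-way repeated-measures (mixed-design) ANOVA tests
the subject curves with scale as the within-subject factor (7 levels by
default) and group as the between-subject factor, followed by pairwise
post-hoc comparisons with Bonferroni correction at individual scales.
Greenhouse-Geisser-corrected p-values are reported alongside uncorrected
ones for the within-subject effects, since sphericity rarely holds for
entropy-by-scale data.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = ["EffectResult", "AnovaResult", "rm_anova", "posthoc_bonferroni"]

log = logging.getLogger(__name__)


@dataclass
class EffectResult:
    """F statistic, degrees of freedom and p-value(s) for one ANOVA effect."""

    name: str
    F: float
    df1: float
    df2: float
    p: float
    p_gg: float | None = None  # Greenhouse-Geisser corrected (within effects)

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p < alpha


@dataclass
class AnovaResult:
    """Scale, group and interaction effects of one mixed-design ANOVA."""

    scale: EffectResult
    group: EffectResult | None
    interaction: EffectResult | None
    alpha: float = 0.05
    scheme_id: int | None = None
    n_subjects_used: int = 0
    n_subjects_excluded: int = 0
    effects: dict = field(default_factory=dict)


def _curves_to_long(
    curves: np.ndarray, group_labels: list[str]
) -> tuple[pd.DataFrame, int]:
    """Long-form table of complete curves; incomplete subjects are excluded."""
    curves = np.asarray(curves, dtype=float)
    complete = np.isfinite(curves).all(axis=1)
    n_excl = int((~complete).sum())
    if n_excl:
        log.info("excluding %d subject(s) with undefined scales from ANOVA", n_excl)
    rows = []
    for s_idx in np.flatnonzero(complete):
        for sc in range(curves.shape[1]):
            rows.append(
                dict(subject=f"s{s_idx}", group=group_labels[s_idx],
                     scale=sc + 1, value=curves[s_idx, sc])
            )
    return pd.DataFrame(rows), n_excl


def rm_anova(
    subject_curves: np.ndarray,
    group_labels: list[str],
    alpha: float = 0.05,
    scheme_id: int | None = None,
) -> AnovaResult:
    """Two-way repeated-measures ANOVA: scale (within) x group (between).

    Parameters
    ----------
    subject_curves
        Array of shape ``(n_subjects, n_scales)``; one MMSE curve per
        subject.  Subjects with any non-finite (flagged) scale are excluded
        listwise.
    group_labels
        Group membership per subject.
    alpha
        Significance level recorded in the result.

    With fewer than two groups the between-subject and interaction effects
    are omitted with a warning and only the scale effect is tested.  A
    between-group effect whose sum of squares is numerically zero (all
    groups identical) is reported as F = 0, p = 1 rather than 0/0.
    """
    subject_curves = np.asarray(subject_curves, dtype=float)
    if subject_curves.ndim != 2:
        raise ValueError("subject_curves must be (n_subjects, n_scales)")
    if len(group_labels) != subject_curves.shape[0]:
        raise ValueError("one group label per subject")
    df, n_excl = _curves_to_long(subject_curves, list(group_labels))
    n_used = df["subject"].nunique()
    groups_present = df["group"].unique()

    def _col(res, row, *names, default=np.nan):
        for name in names:
            if name in res.columns:
                val = row[name]
                return float(val) if np.isfinite(val) else default
        return default

    complete = subject_curves[np.isfinite(subject_curves).all(axis=1)]
    if complete.shape[0] >= 2 and np.allclose(complete, complete[0], atol=1e-12):
        # fully degenerate design: every subject has the identical curve, so
        # there is no between-group or error variance anywhere
        scale_varies = not np.allclose(complete[0], complete[0][0], atol=1e-12)
        scale_eff = EffectResult(
            name="scale", F=np.inf if scale_varies else 0.0,
            df1=float(subject_curves.shape[1] - 1),
            df2=float((n_used - 1) * (subject_curves.shape[1] - 1)),
            p=0.0 if scale_varies else 1.0,
        )
        multi = len(groups_present) >= 2
        zero = EffectResult(name="group", F=0.0, df1=float(len(groups_present) - 1),
                            df2=float(n_used - len(groups_present)), p=1.0)
        inter = EffectResult(name="scale x group", F=0.0, df1=zero.df1 * scale_eff.df1,
                             df2=scale_eff.df2, p=1.0)
        return AnovaResult(scale=scale_eff, group=zero if multi else None,
                           interaction=inter if multi else None, alpha=alpha,
                           scheme_id=scheme_id, n_subjects_used=n_used,
                           n_subjects_excluded=n_excl)

    if len(groups_present) < 2:
        log.warning("fewer than 2 groups: between-subject effect omitted")
        res = pg.rm_anova(data=df, dv="value", within="scale", subject="subject",
                          correction=True, detailed=True)
        row = res.iloc[0]
        scale_eff = EffectResult(
            name="scale", F=float(row["F"]), df1=float(row["DF"]),
            df2=float(res.iloc[1]["DF"]),
            p=_col(res, row, "p_unc", "p-unc"),
            p_gg=_col(res, row, "p_GG_corr", "p-GG-corr", default=None),
        )
        return AnovaResult(scale=scale_eff, group=None, interaction=None,
                           alpha=alpha, scheme_id=scheme_id,
                           n_subjects_used=n_used, n_subjects_excluded=n_excl)

    counts = df.groupby("group")["subject"].nunique()
    if (counts < 2).any():
        raise ValueError(f"need >= 2 subjects per group, got {counts.to_dict()}")

    res = pg.mixed_anova(data=df, dv="value", within="scale", subject="subject",
                         between="group", correction=True)
    res = res.set_index("Source")

    def _effect(source: str, name: str, within: bool) -> EffectResult:
        row = res.loc[source]
        F = float(row["F"])
        p = float(row["p_unc" if "p_unc" in res.columns else "p-unc"])
        if not np.isfinite(F) and float(row["SS"]) <= 1e-12:
            # no variance attributable to the effect at all
            F, p = 0.0, 1.0
        p_gg = None
        if within:
            for col in ("p_GG_corr", "p-GG-corr"):
                if col in res.columns and np.isfinite(row.get(col, np.nan)):
                    p_gg = float(row[col])
                    break
        return EffectResult(name=name, F=F, df1=float(row["DF1"]),
                            df2=float(row["DF2"]), p=p, p_gg=p_gg)

    group_eff = _effect("group", "group", within=False)
    scale_eff = _effect("scale", "scale", within=True)
    inter_eff = _effect("Interaction", "scale x group", within=True)
    return AnovaResult(
        scale=scale_eff, group=group_eff, interaction=inter_eff,
        alpha=alpha, scheme_id=scheme_id,
        n_subjects_used=n_used, n_subjects_excluded=n_excl,
        effects={"scale": scale_eff, "group": group_eff, "interaction": inter_eff},
    )


def posthoc_bonferroni(
    values: np.ndarray, group_labels: list[str]
) -> pd.DataFrame:
    """Pairwise two-sample t-tests with Bonferroni correction.

    ``values`` holds one number per subject (e.g. the MSampEn at one scale).
    Adjusted p-values are ``min(1, p * n_comparisons)`` over the
    ``C(n_groups, 2)`` pairs.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(group_labels):
        raise ValueError("one group label per value")
    groups = sorted(set(group_labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    pairs = list(itertools.combinations(groups, 2))
    n_comp = len(pairs)
    rows = []
    for a, b in pairs:
        xa = values[[g == a for g in group_labels]]
        xb = values[[g == b for g in group_labels]]
        if np.allclose(xa.std(), 0) and np.allclose(xb.std(), 0) and np.allclose(
            xa.mean(), xb.mean()
        ):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(xa, xb)
            t, p = float(t), float(p)
            if not np.isfinite(p):
                p = 1.0
        rows.append(dict(group_a=a, group_b=b, t=t, p_raw=p,
                         p_adj=min(1.0, p * n_comp), n_comparisons=n_comp))
    return pd.DataFrame(rows)
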