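"""Repeated-measures ANOVA, simple effects, Bonferroni contrasts and the
gated decision tree.

The measure tables analyzed here are long-format frames with columns
``subject, ma, tp, measure, value`` and exactly one value per subject x
cell.  All effects are within-subject: each effect is tested against its own
subject x effect interaction mean square, with uncorrected degrees of
freedom (no sphericity correction by default; an optional Greenhouse-Geisser
flag is provided).  Effect size is partial eta squared,
SS_effect / (SS_effect + SS_error); classical eta squared
(SS_effect / SS_total) is reported alongside.

The gated scheme mirrors the study logic: test the MA x TP interaction
first; if it is significant at alpha, test the simple effect of TP at each
MA level (with Bonferroni-corrected pairwise contrasts where significant);
otherwise test the two main effects, following a significant TP main effect
with Bonferroni pairs.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import EmptyCellError, IncompleteDesignError, ParameterError


# ---------------------------------------------------------------------------
# Report containers
# ---------------------------------------------------------------------------

@dataclass
class EffectResult:
    name: str
    F: float
    df: tuple[int, int]
    p: float
    partial_eta_sq: float
    eta_sq: float = float("nan")
    gg_epsilon: float | None = None

    @property
    def significant(self) -> bool:
        return self.p < 0.05

    def format(self) -> str:
        return (f"{self.name}: F({self.df[0]},{self.df[1]}) = {self.F:.3f}, "
                f"p = {self.p:.4g}, etap2 = {self.partial_eta_sq:.3f}")


@dataclass
class PairwiseContrast:
    level_a: str
    level_b: str
    mean_diff: float
    t: float
    df: int
    p_raw: float
    p_adj: float

    def format(self) -> str:
        return (f"{self.level_a} vs {self.level_b}: t({self.df}) = "
                f"{self.t:.3f}, p_adj = {self.p_adj:.4g}")


@dataclass
class AnovaReport:
    effects: dict[str, EffectResult] = field(default_factory=dict)
    pairwise: list[PairwiseContrast] = field(default_factory=list)
    simple_effects: dict[str, "AnovaReport"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "effects": {k: asdict(v) for k, v in self.effects.items()},
            "pairwise": [asdict(c) for c in self.pairwise],
            "simple_effects": {k: v.to_dict()
                               for k, v in self.simple_effects.items()},
        }


@dataclass
class GatedReport:
    """Outcome of the gated decision tree for one measure."""

    measure: str
    alpha: float
    interaction: EffectResult
    branch: str  # 'simple_effects' | 'main_effects'
    main_effects: dict[str, EffectResult] = field(default_factory=dict)
    simple_effects: dict[str, AnovaReport] = field(default_factory=dict)
    pairwise_tp: list[PairwiseContrast] = field(default_factory=list)

    def significant_pairwise(self) -> list[PairwiseContrast]:
        """Every final pairwise contrast the procedure declared significant."""
        out = [c for c in self.pairwise_tp if c.p_adj < self.alpha]
        for rep in self.simple_effects.values():
            out.extend(c for c in rep.pairwise if c.p_adj < self.alpha)
        return out

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "alpha": self.alpha,
            "interaction": asdict(self.interaction),
            "branch": self.branch,
            "main_effects": {k: asdict(v)
                             for k, v in self.main_effects.items()},
            "simple_effects": {k: v.to_dict()
                               for k, v in self.simple_effects.items()},
            "pairwise_tp": [asdict(c) for c in self.pairwise_tp],
        }

    def format(self) -> str:
        lines = [f"measure: {self.measure}",
                 "  interaction " + self.interaction.format(),
                 f"  branch: {self.branch}"]
        for name, eff in self.main_effects.items():
            lines.append("  main " + eff.format())
        for level, rep in self.simple_effects.items():
            for eff in rep.effects.values():
                lines.append(f"  simple[{level}] " + eff.format())
            for c in rep.pairwise:
                lines.append(f"    {c.format()}")
        for c in self.pairwise_tp:
            lines.append("  " + c.format())
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Core decompositions
# ---------------------------------------------------------------------------

def _level_order(series: pd.Series) -> list:
    seen: list = []
    for v in series:
        if v not in seen:
            seen.append(v)
    return seen


def _pivot_cells(table: pd.DataFrame, factors: tuple[str, str] = ("ma", "tp"),
                 dv: str = "value", subject: str = "subject") -> tuple:
    """Balanced (subjects, a, b) array; errors name the missing cell."""
    fa, fb = factors
    subjects = _level_order(table[subject])
    la = _level_order(table[fa])
    lb = _level_order(table[fb])
    grouped = table.set_index([subject, fa, fb])[dv]
    if grouped.index.has_duplicates:
        dup = grouped.index[grouped.index.duplicated()][0]
        raise IncompleteDesignError(
            f"duplicate value for subject {dup[0]!r} cell "
            f"({dup[1]!r}, {dup[2]!r}); expected one value per subject x cell")
    Y = np.empty((len(subjects), len(la), len(lb)))
    for i, s in enumerate(subjects):
        for j, a in enumerate(la):
            for k, b in enumerate(lb):
                try:
                    Y[i, j, k] = grouped.loc[(s, a, b)]
                except KeyError:
                    raise IncompleteDesignError(
                        f"subject {s!r} is missing cell ({a!r}, {b!r})"
                    ) from None
    return Y, subjects, la, lb


def _dust_floor(Y: np.ndarray) -> float:
    """SS below this are rounding dust from arithmetically identical values."""
    peak = float(np.abs(Y).max())
    return (peak ** 2) * Y.size * 1e-24


def _effect(name: str, ss_eff: float, df_eff: int, ss_err: float,
            df_err: int, ss_total: float) -> EffectResult:
    if ss_err <= 0:
        if ss_eff <= 0:
            return EffectResult(name, 0.0, (df_eff, df_err), 1.0, 0.0, 0.0)
        return EffectResult(name, float("inf"), (df_eff, df_err), 0.0,
                            1.0, ss_eff / ss_total if ss_total > 0 else 1.0)
    F = (ss_eff / df_eff) / (ss_err / df_err)
    p = float(sps.f.sf(F, df_eff, df_err))
    etap = ss_eff / (ss_eff + ss_err)
    eta = ss_eff / ss_total if ss_total > 0 else 0.0
    return EffectResult(name, float(F), (df_eff, df_err), p, float(etap),
                        float(eta))


def rm_anova_2way(table: pd.DataFrame, factors: tuple[str, str] = ("ma", "tp"),
                  dv: str = "value", subject: str = "subject",
                  gg_correction: bool = False) -> AnovaReport:
    """Two-way fully within-subject ANOVA on a balanced one-value-per-cell
    table.

    Sums of squares are partitioned into the two main effects and their
    interaction, each tested against its own subject x effect interaction.
    """
    Y, subjects, la, lb = _pivot_cells(table, factors, dv, subject)
    n, a, b = Y.shape
    if n < 2:
        raise ParameterError("subject: at least 2 subjects required")
    grand = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_ab = Y.mean(axis=0)
    m_as = Y.mean(axis=2)
    m_bs = Y.mean(axis=1)

    ss_total = float(((Y - grand) ** 2).sum())
    ss_a = float(n * b * ((m_a - grand) ** 2).sum())
    ss_b = float(n * a * ((m_b - grand) ** 2).sum())
    ss_ab = float(n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
                  .sum())
    ss_as = float(b * ((m_as - m_s[:, None] - m_a[None, :] + grand) ** 2)
                  .sum())
    ss_bs = float(a * ((m_bs - m_s[:, None] - m_b[None, :] + grand) ** 2)
                  .sum())
    resid = (Y - m_ab[None, :, :] - m_as[:, :, None] - m_bs[:, None, :]
             + m_a[None, :, None] + m_b[None, None, :] + m_s[:, None, None]
             - grand)
    ss_abs = float((resid ** 2).sum())

    floor = _dust_floor(Y)
    ss_a, ss_b, ss_ab, ss_as, ss_bs, ss_abs = (
        0.0 if ss < floor else ss
        for ss in (ss_a, ss_b, ss_ab, ss_as, ss_bs, ss_abs))

    fa, fb = factors
    report = AnovaReport()
    report.effects[fa] = _effect(fa, ss_a, a - 1, ss_as, (a - 1) * (n - 1),
                                 ss_total)
    report.effects[fb] = _effect(fb, ss_b, b - 1, ss_bs, (b - 1) * (n - 1),
                                 ss_total)
    report.effects[f"{fa} x {fb}"] = _effect(
        f"{fa} x {fb}", ss_ab, (a - 1) * (b - 1), ss_abs,
        (a - 1) * (b - 1) * (n - 1), ss_total)
    if gg_correction:
        _apply_gg(report.effects[fb], Y.mean(axis=1))
        _apply_gg(report.effects[f"{fa} x {fb}"], None)
    return report


def rm_anova_1way(table: pd.DataFrame, factor: str = "tp", dv: str = "value",
                  subject: str = "subject",
                  gg_correction: bool = False) -> AnovaReport:
    """One-way within-subject ANOVA (subjects x factor, one value per cell)."""
    levels = _level_order(table[factor])
    if len(levels) < 2:
        raise ParameterError(f"{factor}: needs >= 2 levels, got {levels}")
    subjects = _level_order(table[subject])
    grouped = table.set_index([subject, factor])[dv]
    if grouped.index.has_duplicates:
        raise IncompleteDesignError(
            "expected one value per subject x level")
    Y = np.empty((len(subjects), len(levels)))
    for i, s in enumerate(subjects):
        for j, l in enumerate(levels):
            try:
                Y[i, j] = grouped.loc[(s, l)]
            except KeyError:
                raise IncompleteDesignError(
                    f"subject {s!r} is missing level {l!r}") from None
    n, b = Y.shape
    if n < 2:
        raise ParameterError("subject: at least 2 subjects required")
    grand = Y.mean()
    m_s = Y.mean(axis=1)
    m_b = Y.mean(axis=0)
    ss_total = float(((Y - grand) ** 2).sum())
    ss_b = float(n * ((m_b - grand) ** 2).sum())
    ss_err = float(((Y - m_s[:, None] - m_b[None, :] + grand) ** 2).sum())
    floor = _dust_floor(Y)
    ss_b = 0.0 if ss_b < floor else ss_b
    ss_err = 0.0 if ss_err < floor else ss_err
    report = AnovaReport()
    report.effects[factor] = _effect(factor, ss_b, b - 1, ss_err,
                                     (b - 1) * (n - 1), ss_total)
    if gg_correction:
        _apply_gg(report.effects[factor], Y)
    return report


def _apply_gg(effect: EffectResult, Y: np.ndarray | None) -> None:
    """Greenhouse-Geisser epsilon adjustment of df and p (optional)."""
    if Y is None or Y.shape[1] < 3:
        return
    S = np.cov(Y, rowvar=False)
    k = S.shape[0]
    mean_diag = np.trace(S) / k
    mean_all = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(S ** 2) - 2 * k * np.sum(row_means ** 2)
                     + k ** 2 * mean_all ** 2)
    if den <= 0:
        return
    eps = float(np.clip(num / den, 1.0 / (k - 1), 1.0))
    d1, d2 = effect.df
    effect.gg_epsilon = eps
    effect.p = float(sps.f.sf(effect.F, d1 * eps, d2 * eps))


def simple_effects_tp(table: pd.DataFrame, within_ma_level: str,
                      factor: str = "tp", ma_factor: str = "ma",
                      dv: str = "value", subject: str = "subject"
                      ) -> AnovaReport:
    """One-way repeated ANOVA of TP restricted to one MA level.

    Computable unconditionally; the gate (interaction significance) is the
    caller's policy, applied in :func:`run_gated_analysis`.
    """
    sub = table[table[ma_factor] == within_ma_level]
    if sub.empty:
        raise ParameterError(
            f"{ma_factor}: no rows at level {within_ma_level!r}")
    return rm_anova_1way(sub, factor=factor, dv=dv, subject=subject)


def _paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Paired t with the degenerate zero-variance convention (p = 1)."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = len(d)
    if n < 2:
        raise ParameterError("pairs: at least 2 paired observations required")
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, n - 1, 1.0
        return float("inf") if d.mean() > 0 else float("-inf"), n - 1, 0.0
    t = d.mean() / (sd / np.sqrt(n))
    p = float(2 * sps.t.sf(abs(t), n - 1))
    return float(t), n - 1, p


def pairwise_bonferroni(table: pd.DataFrame, factor: str = "tp",
                        levels=None, dv: str = "value",
                        subject: str = "subject") -> list[PairwiseContrast]:
    """Paired t-tests over all level pairs; p_adj = min(1, p * n_pairs)."""
    if levels is None:
        levels = _level_order(table[factor])
    if len(levels) < 2:
        raise ParameterError(f"{factor}: needs >= 2 levels")
    subjects = _level_order(table[subject])
    wide = table.pivot_table(index=subject, columns=factor, values=dv,
                             aggfunc="first").loc[subjects]
    if wide[list(levels)].isna().any().any():
        raise IncompleteDesignError(
            f"{factor}: unpaired data (missing subject x level values)")
    pairs = list(combinations(levels, 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        t, df, p = _paired_t(wide[a].to_numpy(), wide[b].to_numpy())
        out.append(PairwiseContrast(
            level_a=str(a), level_b=str(b),
            mean_diff=float(wide[a].mean() - wide[b].mean()),
            t=t, df=df, p_raw=p, p_adj=min(1.0, p * m)))
    return out


# ---------------------------------------------------------------------------
# The gated decision tree
# ---------------------------------------------------------------------------

def run_gated_analysis(table: pd.DataFrame, alpha: float = 0.05,
                       measure: str | None = None,
                       gg_correction: bool = False) -> GatedReport:
    """Execute the interaction-gated testing scheme on one measure's table.

    Interaction significant at ``alpha`` -> simple effect of TP at each MA
    level, with Bonferroni pairs where the simple effect is significant.
    Otherwise -> MA and TP main effects, with Bonferroni pairs following a
    significant TP main effect.
    """
    if measure is None:
        uniq = table["measure"].unique() if "measure" in table else ["value"]
        if len(uniq) != 1:
            raise ParameterError(
                f"measure: table holds several measures {list(uniq)}; "
                "pass measure= to select one")
        measure = str(uniq[0])
    if "measure" in table:
        table = table[table["measure"] == measure]
        if table.empty:
            raise ParameterError(f"measure: no rows for {measure!r}")
    two_way = rm_anova_2way(table, gg_correction=gg_correction)
    interaction = two_way.effects["ma x tp"]
    report = GatedReport(measure=measure, alpha=alpha,
                         interaction=interaction, branch="")
    if interaction.p < alpha:
        report.branch = "simple_effects"
        for level in _level_order(table["ma"]):
            simple = simple_effects_tp(table, level)
            eff = simple.effects["tp"]
            if eff.p < alpha:
                simple.pairwise = pairwise_bonferroni(
                    table[table["ma"] == level])
            report.simple_effects[level] = simple
    else:
        report.branch = "main_effects"
        report.main_effects["ma"] = two_way.effects["ma"]
        report.main_effects["tp"] = two_way.effects["tp"]
        if two_way.effects["tp"].p < alpha:
            # pairwise TP contrasts on cell values collapsed over MA
            collapsed = (table.groupby(["subject", "tp"], sort=False)["value"]
                         .mean().reset_index())
            report.pairwise_tp = pairwise_bonferroni(collapsed)
    return report


# ---------------------------------------------------------------------------
# Behavioral statistics
# ---------------------------------------------------------------------------

def summarize_behavior(frame: pd.DataFrame,
                       anticipation_floor_s: float = 0.080) -> pd.DataFrame:
    """Per subject x cell: mean RT over qualified trials and accuracy rate.

    Accuracy is the ratio of qualified trials (correct and RT at or above the
    anticipation floor) to total trials in the cell.
    """
    df = frame.copy()
    df["qualified"] = df["correct"] & (df["rt_s"] >= anticipation_floor_s)
    grouped = df.groupby(["subject", "ma", "tp"], sort=False)
    out = grouped.apply(
        lambda g: pd.Series({
            "rt_mean_s": g.loc[g["qualified"], "rt_s"].mean(),
            "accuracy": g["qualified"].mean(),
        }), include_groups=False)
    return out.reset_index()


def behavior_stats(behavior, anticipation_floor_s: float = 0.080,
                   alpha: float = 0.05) -> dict:
    """The behavioral testing scheme on a long behavior table.

    Paired t between the two MA levels on subject means (RT and accuracy),
    then per MA level a one-way repeated ANOVA across TP with Bonferroni
    pairs.  Zero-variance measures are reported with the degenerate
    convention (F = 0 / p = 1) so batch runs stay total.
    """
    frame = behavior.frame if hasattr(behavior, "frame") else behavior
    summary = summarize_behavior(frame, anticipation_floor_s)
    if summary["rt_mean_s"].isna().any():
        bad = summary.loc[summary["rt_mean_s"].isna(),
                          ["subject", "ma", "tp"]].iloc[0]
        raise EmptyCellError(
            f"no qualified trials for subject {bad['subject']!r} cell "
            f"({bad['ma']!r}, {bad['tp']!r})")
    ma_levels = _level_order(summary["ma"])
    out: dict = {"summary": summary, "paired": {}, "anova": {}}
    for dv in ("rt_mean_s", "accuracy"):
        if len(ma_levels) == 2:
            per_subj = summary.pivot_table(index="subject", columns="ma",
                                           values=dv, aggfunc="mean")
            t, df, p = _paired_t(per_subj[ma_levels[0]].to_numpy(),
                                 per_subj[ma_levels[1]].to_numpy())
            out["paired"][dv] = PairwiseContrast(
                level_a=str(ma_levels[0]), level_b=str(ma_levels[1]),
                mean_diff=float(per_subj[ma_levels[0]].mean()
                                - per_subj[ma_levels[1]].mean()),
                t=t, df=df, p_raw=p, p_adj=p)
        for ma in ma_levels:
            sub = summary[summary["ma"] == ma].rename(columns={dv: "value"})
            rep = rm_anova_1way(sub[["subject", "tp", "value"]])
            if rep.effects["tp"].p < alpha and np.isfinite(
                    rep.effects["tp"].F):
                rep.pairwise = pairwise_bonferroni(
                    sub[["subject", "tp", "value"]])
            out["anova"][(dv, ma)] = rep
    return out
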