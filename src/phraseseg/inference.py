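"""Mixed-design inferential statistics: classical univariate mixed ANOVAs
with partial eta squared, paired/independent t-tests with Cohen's d, a
summary-statistics t-test, and an exact/approximate Wilcoxon signed-rank test.

The ANOVA supports one optional between-subjects factor and one or two
within-subjects factors on a balanced long-format table (one observation per
subject x within-cell; average repeated observations, e.g. over stimuli,
before calling).  F ratios use the classical error terms: between effects
are tested against subjects-within-groups, each within effect (and its
interactions with the between factor) against its factor-by-subjects
interaction.  Degrees of freedom are uncorrected by default;
Greenhouse-Geisser correction is available via a flag.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DesignError, DomainError

__all__ = [
    "AnovaResult",
    "TestResult",
    "mixed_anova",
    "mixed_anova_from_array",
    "anova_frame",
    "paired_t",
    "independent_t",
    "summary_t",
    "wilcoxon_signed_rank",
    "analyze_experiment",
]


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float
    ss_effect: float = math.nan
    ss_error: float = math.nan
    gg_epsilon: float | None = None


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int | None
    p: float
    effect_size: float
    z: float | None = None
    degenerate: bool = False
    note: str = ""


# ---------------------------------------------------------------------------
# Mixed ANOVA
# ---------------------------------------------------------------------------

def mixed_anova_from_array(
    y: np.ndarray,
    groups: np.ndarray | None = None,
    *,
    factor_names: Sequence[str] = ("between", "within1", "within2"),
    gg_correction: bool = False,
) -> list[AnovaResult]:
    """Mixed ANOVA on an ``(n_subjects, b, c)`` (or ``(n_subjects, b)``)
    array of cell scores; ``groups`` assigns each subject to a between level.

    Returns one :class:`AnovaResult` per estimable effect, in a fixed order
    (between, within1, between x within1, within2, ..., three-way).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 2:
        y = y[:, :, None]
    if y.ndim != 3:
        raise DesignError("cell-score array must be (subjects, within1[, within2])")
    if not np.isfinite(y).all():
        raise DesignError("cell scores contain missing values; design must be complete")
    n_subj, b, c = y.shape
    if groups is None:
        groups = np.zeros(n_subj, dtype=int)
    groups = np.asarray(groups)
    levels, g_idx = np.unique(groups, return_inverse=True)
    a = len(levels)
    counts = np.bincount(g_idx)
    if n_subj < 2 or counts.min() < 2:
        raise DesignError("need at least 2 subjects per group")
    if counts.max() != counts.min():
        raise DesignError(f"unbalanced between-groups design (group sizes {counts.tolist()})")
    n = int(counts[0])

    gm = y.mean()
    m_s = y.mean(axis=(1, 2))  # subject means
    m_a = np.array([m_s[g_idx == i].mean() for i in range(a)])
    m_b = y.mean(axis=(0, 2))
    m_c = y.mean(axis=(0, 1))
    m_ab = np.stack([y[g_idx == i].mean(axis=(0, 2)) for i in range(a)])  # (a, b)
    m_ac = np.stack([y[g_idx == i].mean(axis=(0, 1)) for i in range(a)])  # (a, c)
    m_bc = y.mean(axis=0)  # (b, c)
    m_abc = np.stack([y[g_idx == i].mean(axis=0) for i in range(a)])  # (a, b, c)
    m_sb = y.mean(axis=2)  # (subj, b)
    m_sc = y.mean(axis=1)  # (subj, c)

    ss = {}
    ss["A"] = n * b * c * float(((m_a - gm) ** 2).sum())
    ss["S"] = b * c * float(((m_s - m_a[g_idx]) ** 2).sum())
    ss["B"] = n_subj * c * float(((m_b - gm) ** 2).sum())
    ss["AB"] = n * c * float(
        ((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2).sum()
    )
    ss["BS"] = c * float(
        ((m_sb - m_s[:, None] - m_ab[g_idx] + m_a[g_idx, None]) ** 2).sum()
    )
    ss["C"] = n_subj * b * float(((m_c - gm) ** 2).sum())
    ss["AC"] = n * b * float(
        ((m_ac - m_a[:, None] - m_c[None, :] + gm) ** 2).sum()
    )
    ss["CS"] = b * float(
        ((m_sc - m_s[:, None] - m_ac[g_idx] + m_a[g_idx, None]) ** 2).sum()
    )
    ss["BC"] = n_subj * float(
        ((m_bc - m_b[:, None] - m_c[None, :] + gm) ** 2).sum()
    )
    ss["ABC"] = n * float(
        (
            (
                m_abc
                - m_ab[:, :, None]
                - m_ac[:, None, :]
                - m_bc[None, :, :]
                + m_a[:, None, None]
                + m_b[None, :, None]
                + m_c[None, None, :]
                - gm
            )
            ** 2
        ).sum()
    )
    ss_total = float(((y - gm) ** 2).sum())
    ss["BCS"] = ss_total - sum(
        ss[k] for k in ("A", "S", "B", "AB", "BS", "C", "AC", "CS", "BC", "ABC")
    )
    ss["BCS"] = max(ss["BCS"], 0.0)

    df = {
        "A": a - 1,
        "S": a * (n - 1),
        "B": b - 1,
        "AB": (a - 1) * (b - 1),
        "BS": a * (n - 1) * (b - 1),
        "C": c - 1,
        "AC": (a - 1) * (c - 1),
        "CS": a * (n - 1) * (c - 1),
        "BC": (b - 1) * (c - 1),
        "ABC": (a - 1) * (b - 1) * (c - 1),
        "BCS": a * (n - 1) * (b - 1) * (c - 1),
    }

    name_a, name_b, name_c = factor_names
    plan = [
        ("A", name_a, "S"),
        ("B", name_b, "BS"),
        ("AB", f"{name_a} x {name_b}", "BS"),
        ("C", name_c, "CS"),
        ("AC", f"{name_a} x {name_c}", "CS"),
        ("BC", f"{name_b} x {name_c}", "BCS"),
        ("ABC", f"{name_a} x {name_b} x {name_c}", "BCS"),
    ]

    eps_b = eps_c = None
    if gg_correction:
        if b > 2:
            eps_b = _gg_epsilon(m_sb, g_idx, a)
        if c > 2:
            eps_c = _gg_epsilon(m_sc, g_idx, a)

    results = []
    for key, label, err in plan:
        if df[key] == 0:
            continue
        ms_eff = ss[key] / df[key]
        ms_err = ss[err] / df[err] if df[err] > 0 else math.nan
        if ss[key] <= 1e-10 * max(ss_total, 1e-30):
            f = 0.0
        elif ms_err > 0:
            f = ms_eff / ms_err
        else:
            f = math.inf
        eps = None
        if gg_correction:
            if err == "BS":
                eps = eps_b
            elif err == "CS":
                eps = eps_c
            elif err == "BCS" and (eps_b or eps_c):
                eps = (eps_b or 1.0) * (eps_c or 1.0)
        if eps is not None:
            p = float(sps.f.sf(f, df[key] * eps, df[err] * eps))
        else:
            p = float(sps.f.sf(f, df[key], df[err]))
        denom = ss[key] + ss[err]
        results.append(
            AnovaResult(
                effect=label,
                F=float(f),
                df_num=df[key],
                df_den=df[err],
                p=p,
                partial_eta_sq=(ss[key] / denom if denom > 0 else 0.0),
                ss_effect=ss[key],
                ss_error=ss[err],
                gg_epsilon=eps,
            )
        )
    return results


def _gg_epsilon(scores: np.ndarray, g_idx: np.ndarray, a: int) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance of
    one within factor's subject x level scores."""
    k = scores.shape[1]
    cov = np.zeros((k, k))
    for i in range(a):
        sub = scores[g_idx == i]
        cov += np.cov(sub, rowvar=False) * (sub.shape[0] - 1)
    cov /= scores.shape[0] - a
    mean_diag = np.trace(cov) / k
    mean_all = cov.mean()
    row_means = cov.mean(axis=1)
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (
        (cov**2).sum() - 2 * k * (row_means**2).sum() + k**2 * mean_all**2
    )
    if den <= 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / (k - 1))))


def mixed_anova(
    table: pd.DataFrame,
    dv: str,
    within_factors: Sequence[str],
    between_factor: str | None = None,
    *,
    subject: str = "participant_id",
    gg_correction: bool = False,
) -> list[AnovaResult]:
    """Mixed ANOVA on a balanced long-format table.

    ``table`` must contain one row per subject x within-cell (average any
    replicates first); every subject must have all within cells and groups
    must be equal-sized, otherwise a :class:`DesignError` is raised.
    """
    within_factors = list(within_factors)
    if not 1 <= len(within_factors) <= 2:
        raise DesignError("one or two within factors are supported")
    cols = [subject, dv, *within_factors] + ([between_factor] if between_factor else [])
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise DesignError(f"table is missing columns {missing}")
    dup = table.groupby([subject, *within_factors], sort=False).size()
    if (dup > 1).any():
        raise DesignError(
            "multiple observations per subject x within-cell; average them first"
        )

    wide = table.pivot_table(
        index=subject, columns=within_factors, values=dv, sort=True
    ).sort_index()
    if wide.isna().any().any():
        raise DesignError("incomplete design: some subjects are missing within cells")
    subjects = wide.index
    w1_levels = sorted(table[within_factors[0]].unique())
    b = len(w1_levels)
    if len(within_factors) == 2:
        w2_levels = sorted(table[within_factors[1]].unique())
        c = len(w2_levels)
        y = wide.loc[:, list(itertools.product(w1_levels, w2_levels))].to_numpy()
        y = y.reshape(len(subjects), b, c)
    else:
        y = wide.loc[:, w1_levels].to_numpy().reshape(len(subjects), b, 1)

    if between_factor:
        per_subject = table.groupby(subject, sort=True)[between_factor].agg("unique")
        if (per_subject.str.len() > 1).any():
            raise DesignError("a subject appears in more than one between-group level")
        groups = per_subject.str[0].loc[subjects].to_numpy()
    else:
        groups = None
    names = (
        between_factor or "between",
        within_factors[0],
        within_factors[1] if len(within_factors) == 2 else "within2",
    )
    return mixed_anova_from_array(y, groups, factor_names=names, gg_correction=gg_correction)


def anova_frame(results: Sequence[AnovaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "effect": r.effect,
                "F": r.F,
                "df_num": r.df_num,
                "df_den": r.df_den,
                "p": r.p,
                "partial_eta_sq": r.partial_eta_sq,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------

def paired_t(x, y) -> TestResult:
    """Two-sided paired t-test; Cohen's d = mean(diff) / sd(diff)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise DomainError("paired samples must be equal-length with n >= 2")
    diff = x - y
    sd = diff.std(ddof=1)
    n = diff.size
    if sd == 0:
        if diff.mean() == 0:
            return TestResult(0.0, n - 1, 1.0, 0.0, degenerate=True, note="zero variance")
        t = math.copysign(math.inf, diff.mean())
        return TestResult(t, n - 1, 0.0, t, degenerate=True, note="zero variance")
    t = diff.mean() / (sd / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return TestResult(float(t), n - 1, p, float(diff.mean() / sd))


def independent_t(group_a, group_b, *, pooled: bool = True) -> TestResult:
    """Two-sided independent-samples t-test; Cohen's d uses the pooled SD."""
    xa = np.asarray(group_a, dtype=float)
    xb = np.asarray(group_b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise DomainError("need n >= 2 per sample")
    va, vb = xa.var(ddof=1), xb.var(ddof=1)
    if va == 0 and vb == 0:
        same = xa.mean() == xb.mean()
        stat = 0.0 if same else math.copysign(math.inf, xa.mean() - xb.mean())
        return TestResult(stat, xa.size + xb.size - 2, 1.0 if same else 0.0, stat, degenerate=True, note="zero variance")
    res = sps.ttest_ind(xa, xb, equal_var=pooled)
    na, nb = xa.size, xb.size
    sp = math.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    d = (xa.mean() - xb.mean()) / sp
    return TestResult(float(res.statistic), int(round(float(res.df))), float(res.pvalue), float(d))


def summary_t(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> TestResult:
    """Pooled-variance t-test from summary statistics only; algebraically
    identical to :func:`independent_t` on the raw data."""
    if n_a < 2 or n_b < 2:
        raise DomainError("need n >= 2 per sample")
    if sd_a <= 0 or sd_b <= 0:
        raise DomainError("standard deviations must be positive")
    res = sps.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=True)
    sp = math.sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2))
    d = (mean_a - mean_b) / sp
    return TestResult(float(res.statistic), n_a + n_b - 2, float(res.pvalue), float(d))


# ---------------------------------------------------------------------------
# Wilcoxon signed rank
# ---------------------------------------------------------------------------

_EXACT_N_MAX = 25


def wilcoxon_signed_rank(x, y=None) -> TestResult:
    """Two-sided Wilcoxon signed-rank test.

    ``x`` may be paired differences, or first-sample values with ``y``.  Zero
    differences are dropped and tied absolute differences receive averaged
    ranks.  For n <= 25 the two-sided p is exact (sign-flip enumeration via a
    rank-sum convolution, valid under ties); above that a normal
    approximation with tie correction is used.  The reported statistic is the
    smaller of the two signed-rank sums; ``effect_size`` is r = |Z| / sqrt(n).
    """
    diffs = np.asarray(x, dtype=float)
    if y is not None:
        diffs = diffs - np.asarray(y, dtype=float)
    if diffs.size < 1:
        raise DomainError("need at least one pair")
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        return TestResult(0.0, None, 1.0, 0.0, z=0.0, degenerate=True, note="all differences zero")
    ranks = sps.rankdata(np.abs(diffs))
    w_pos = float(ranks[diffs > 0].sum())
    w_neg = float(ranks[diffs < 0].sum())
    w = min(w_pos, w_neg)
    total = n * (n + 1) / 2.0

    mean_w = total / 2.0
    tie_counts = np.unique(ranks, return_counts=True)[1]
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
    z = (w - mean_w) / math.sqrt(var_w) if var_w > 0 else 0.0

    if n <= _EXACT_N_MAX:
        p = _exact_signed_rank_p(ranks, w)
    else:
        p = min(1.0, 2.0 * float(sps.norm.cdf(z)))
    return TestResult(w, None, p, abs(z) / math.sqrt(n), z=float(z))


def _exact_signed_rank_p(ranks: np.ndarray, w_small: float) -> float:
    """Exact two-sided p: distribution of the negative-rank sum over all 2^n
    sign assignments, by integer convolution (ranks doubled to clear ties)."""
    units = np.rint(ranks * 2).astype(int)
    total = int(units.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for u in units:
        shifted = np.zeros_like(counts)
        shifted[u:] = counts[: total + 1 - u]
        counts = counts + shifted
    counts /= counts.sum()
    w_units = int(round(w_small * 2))
    lower = counts[: w_units + 1].sum()
    upper = counts[total - w_units :].sum()
    return float(min(1.0, lower + upper))


# ---------------------------------------------------------------------------
# Experiment-level orchestration
# ---------------------------------------------------------------------------

def analyze_experiment(
    scores: pd.DataFrame,
    seglens: pd.DataFrame,
    *,
    confidence: pd.DataFrame | None = None,
    alpha: float = 0.05,
    gg_correction: bool = False,
    holm: bool = False,
) -> dict:
    """The full inferential layer on long-format score and segment tables.

    ``scores`` needs columns participant_id, instruction, stimulus_id,
    version, model, score; ``seglens`` needs participant_id, instruction,
    stimulus_id, version, mean_len_ms, sd_len_ms.  The stimulus dimension is
    collapsed by averaging before each ANOVA.  Per-model 2x2 follow-ups (and
    per-instruction paired t-tests per model) run only when the three-way
    interaction is significant at ``alpha``.
    """
    for col in ("participant_id", "instruction", "version", "model", "score"):
        if col not in scores.columns:
            raise DesignError(f"scores table is missing column {col!r}")
    out: dict = {}

    # --- segment length: 2 (version, within) x 2 (instruction, between) ---
    seg_cells = (
        seglens.groupby(["participant_id", "instruction", "version"], as_index=False)[
            ["mean_len_ms", "sd_len_ms"]
        ]
        .mean()
    )
    out["seglen_mean"] = anova_frame(
        mixed_anova(seg_cells, "mean_len_ms", ["version"], "instruction", gg_correction=gg_correction)
    )
    out["seglen_sd"] = anova_frame(
        mixed_anova(seg_cells, "sd_len_ms", ["version"], "instruction", gg_correction=gg_correction)
    )

    # --- matching: 2 (version) x 7 (model) within, 2 (instruction) between ---
    score_cells = (
        scores.groupby(
            ["participant_id", "instruction", "version", "model"], as_index=False
        )["score"].mean()
    )
    matching = mixed_anova(
        score_cells, "score", ["version", "model"], "instruction", gg_correction=gg_correction
    )
    out["matching"] = anova_frame(matching)

    three_way = next(
        (r for r in matching if r.effect == "instruction x version x model"), None
    )
    gate_open = three_way is not None and three_way.p < alpha
    out["three_way_significant"] = gate_open

    per_model_rows = []
    followup_rows = []
    if gate_open:
        for model, sub in score_cells.groupby("model", sort=True):
            res = mixed_anova(sub, "score", ["version"], "instruction")
            inter = next(r for r in res if r.effect == "instruction x version")
            per_model_rows.append(
                {
                    "model": model,
                    "effect": inter.effect,
                    "F": inter.F,
                    "df_num": inter.df_num,
                    "df_den": inter.df_den,
                    "p": inter.p,
                    "partial_eta_sq": inter.partial_eta_sq,
                }
            )
            for instr, isub in sub.groupby("instruction", sort=True):
                wide = isub.pivot(index="participant_id", columns="version", values="score")
                if {"natural", "delexicalized"}.issubset(wide.columns):
                    t = paired_t(wide["natural"], wide["delexicalized"])
                    followup_rows.append(
                        {
                            "model": model,
                            "instruction": instr,
                            "t": t.statistic,
                            "df": t.df,
                            "p": t.p,
                            "d": t.effect_size,
                        }
                    )
    out["per_model"] = pd.DataFrame(
        per_model_rows,
        columns=["model", "effect", "F", "df_num", "df_den", "p", "partial_eta_sq"],
    )
    followups = pd.DataFrame(
        followup_rows, columns=["model", "instruction", "t", "df", "p", "d"]
    )
    if holm and not followups.empty:
        followups["p_holm"] = _holm(followups["p"].to_numpy())
    out["followup_t"] = followups

    if confidence is not None:
        conf_cells = confidence.groupby(
            ["participant_id", "instruction", "version"], as_index=False
        )["confidence"].mean()
        out["confidence"] = anova_frame(
            mixed_anova(conf_cells, "confidence", ["version"], "instruction")
        )
    return out


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
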