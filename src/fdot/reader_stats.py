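"""Reader-study diagnostic statistics for dichotomized image interpretation.

Two radiologists rate each subject "positive" or "negative" per modality
(DBT alone, DOT alone, fused); truth is cancer / no cancer.  This module
computes the 2x2 accuracy metrics with Wilson score confidence intervals,
the single-operating-point AUC ((sensitivity + specificity)/2, identical to
the Mann-Whitney statistic of binary ratings) with its DeLong interval,
multi-rater Fleiss kappa (plus the two-rater Cohen form) with a percentile
bootstrap CI, and the paired tests: exact McNemar on discordant calls,
Fisher's exact test, and the paired DeLong test for correlated AUCs.

Ratings travel as a tidy table (subject_id, truth, reader, modality, call);
a small generator simulates such tables with controllable accuracy and
inter-reader correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "DiagnosticTable",
    "AgreementResult",
    "diagnostic_metrics",
    "binary_auc",
    "fleiss_kappa",
    "cohen_kappa",
    "paired_tests",
    "ratings_from_calls",
    "simulate_ratings",
    "load_ratings_csv",
    "save_ratings_csv",
]

RATING_COLUMNS = ["subject_id", "truth", "reader", "modality", "call"]


@dataclass(frozen=True)
class DiagnosticTable:
    """2x2 counts: tp/fn split the diseased, fp/tn the non-diseased."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_healthy(self) -> int:
        return self.fp + self.tn

    @classmethod
    def from_ratings(cls, ratings: pd.DataFrame, reader, modality) -> "DiagnosticTable":
        sub = ratings[(ratings.reader == reader) & (ratings.modality == modality)]
        pos = sub.call.astype(bool)
        truth = sub.truth.astype(bool)
        return cls(
            tp=int((pos & truth).sum()),
            fp=int((pos & ~truth).sum()),
            fn=int((~pos & truth).sum()),
            tn=int((~pos & ~truth).sum()),
        )


def _proportion_metric(k: int, n: int) -> dict | None:
    """Percent metric with Wilson 95% CI; None when the denominator is 0."""
    if n == 0:
        return None
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return {
        "value": 100.0 * k / n,
        "ci_low": 100.0 * lo,
        "ci_high": 100.0 * hi,
        "n": n,
    }


def diagnostic_metrics(t: DiagnosticTable, ci_method: str = "wilson") -> dict:
    """Sensitivity / specificity / PPV / NPV in percent with 95% CIs.

    Wilson score intervals by default (they reproduce the printed clinical
    intervals, e.g. 12/13 -> 92.3 (66.7-98.6)); ``ci_method='beta'`` gives
    exact Clopper-Pearson instead.  Zero-denominator metrics are reported as
    None (undefined), never as 0.
    """
    if ci_method not in ("wilson", "beta"):
        raise ValueError("ci_method must be 'wilson' or 'beta'")

    def prop(k, n):
        if n == 0:
            return None
        lo, hi = proportion_confint(k, n, alpha=0.05, method=ci_method)
        return {"value": 100.0 * k / n, "ci_low": 100.0 * lo,
                "ci_high": 100.0 * hi, "n": n}

    return {
        "sensitivity": prop(t.tp, t.tp + t.fn),
        "specificity": prop(t.tn, t.tn + t.fp),
        "ppv": prop(t.tp, t.tp + t.fp),
        "npv": prop(t.tn, t.tn + t.fn),
    }


def _placements(t: DiagnosticTable):
    """Per-subject placement values of the binary rating versus truth
    (mid-rank convention); diseased placements average to the AUC."""
    sens = t.tp / t.n_diseased
    spec = t.tn / t.n_healthy
    v_dis = np.concatenate(
        [
            np.full(t.tp, spec + (1.0 - spec) / 2.0),
            np.full(t.fn, spec / 2.0),
        ]
    )
    # healthy placements: fraction of diseased rated lower + half ties
    v_hea = np.concatenate(
        [
            np.full(t.fp, t.fn / t.n_diseased + t.tp / (2.0 * t.n_diseased)),
            np.full(t.tn, t.fn / (2.0 * t.n_diseased)),
        ]
    )
    return v_dis, v_hea


def binary_auc(t: DiagnosticTable) -> dict:
    """Single-operating-point AUC with DeLong standard error and 95% CI.

    Computed both as the trapezoid (sens + spec)/2 and as the Mann-Whitney
    statistic of the binary ratings; the two are asserted equal.
    """
    if t.n_diseased == 0 or t.n_healthy == 0:
        raise ValueError("both diseased and healthy strata must be non-empty")
    sens = t.tp / t.n_diseased
    spec = t.tn / t.n_healthy
    auc_trap = (sens + spec) / 2.0
    v_dis, v_hea = _placements(t)
    auc_mw = float(v_dis.mean())
    assert abs(auc_trap - auc_mw) < 1e-12, "trapezoid and Mann-Whitney AUC differ"
    s10 = float(np.var(v_dis, ddof=1)) if t.n_diseased > 1 else 0.0
    s01 = float(np.var(1.0 - v_hea, ddof=1)) if t.n_healthy > 1 else 0.0
    se = float(np.sqrt(s10 / t.n_diseased + s01 / t.n_healthy))
    z = sps.norm.ppf(0.975)
    return {
        "auc": auc_trap,
        "se": se,
        "ci_low": max(0.0, auc_trap - z * se),
        "ci_high": min(1.0, auc_trap + z * se),
    }


# ---------------------------------------------------------------------------
# Agreement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgreementResult:
    kappa: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if np.isfinite(self.kappa) and not -1.0 - 1e-12 <= self.kappa <= 1.0 + 1e-12:
            raise ValueError("kappa outside [-1, 1]")


def _subject_table(ratings: pd.DataFrame, modality) -> np.ndarray:
    """(n_subjects, 2) counts of negative/positive calls per subject."""
    sub = ratings[ratings.modality == modality]
    if sub.empty:
        raise ValueError(f"no ratings for modality {modality!r}")
    piv = (
        sub.assign(call=sub.call.astype(int))
        .pivot_table(index="subject_id", columns="call", values="reader",
                     aggfunc="count", fill_value=0)
        .reindex(columns=[0, 1], fill_value=0)
    )
    counts = piv.to_numpy()
    if counts.sum(axis=1).min() < 2:
        raise ValueError("every subject needs at least 2 raters")
    return counts


def _fleiss_from_counts(counts: np.ndarray) -> float:
    p_cat = counts.sum(axis=0) / counts.sum()
    pe = float(np.sum(p_cat**2))
    if pe >= 1.0:
        return float("nan")  # degenerate: all ratings in one category
    return float(_sm_fleiss(counts, method="fleiss"))


def fleiss_kappa(
    ratings: pd.DataFrame,
    modality,
    n_boot: int = 2000,
    seed: int = 0,
) -> AgreementResult:
    """Fleiss' multi-rater kappa on the binary calls of one modality, with a
    percentile bootstrap CI over subjects (fixed seed, reproducible).

    When every rater assigns the same single category to all subjects the
    chance agreement is 1 and kappa is undefined; reported as NaN.
    """
    counts = _subject_table(ratings, modality)
    kappa = _fleiss_from_counts(counts)
    rng = np.random.default_rng(seed)
    n = len(counts)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        sample = counts[rng.integers(0, n, n)]
        boots[b] = _fleiss_from_counts(sample)
    finite = boots[np.isfinite(boots)]
    if len(finite) == 0:
        lo = hi = float("nan")
    else:
        lo, hi = np.percentile(finite, [2.5, 97.5])
    return AgreementResult(
        kappa=kappa, ci_low=float(lo), ci_high=float(hi),
        n_boot=n_boot, seed=seed,
    )


def cohen_kappa(ratings: pd.DataFrame, modality, readers=None) -> float:
    """Two-rater Cohen's kappa (product marginals), the form clinical
    packages report for a pair of readers."""
    sub = ratings[ratings.modality == modality]
    readers = readers or sorted(sub.reader.unique())
    if len(readers) != 2:
        raise ValueError("cohen_kappa needs exactly two readers")
    a = sub[sub.reader == readers[0]].set_index("subject_id").call.astype(bool)
    b = sub[sub.reader == readers[1]].set_index("subject_id").call.astype(bool)
    b = b.reindex(a.index)
    n = len(a)
    po = float((a.values == b.values).mean())
    pa, pb = a.mean(), b.mean()
    pe = float(pa * pb + (1 - pa) * (1 - pb))
    if pe >= 1.0:
        return float("nan")
    return (po - pe) / (1.0 - pe)


# ---------------------------------------------------------------------------
# Paired comparisons
# ---------------------------------------------------------------------------


def _mcnemar_exact(b: int, c: int) -> float:
    """Exact binomial McNemar on (b, c) discordant pairs; p = 1 when there
    are none (documented convention)."""
    n = b + c
    if n == 0:
        return 1.0
    res = sps.binomtest(min(b, c), n, 0.5, alternative="two-sided")
    return float(min(res.pvalue, 1.0))


def _delong_paired(calls_a, calls_b, truth) -> dict:
    """Paired DeLong test for two correlated binary-rating AUCs."""
    truth = np.asarray(truth, dtype=bool)
    va, vh_a = _placement_vectors(np.asarray(calls_a, dtype=float), truth)
    vb, vh_b = _placement_vectors(np.asarray(calls_b, dtype=float), truth)
    m, n = truth.sum(), (~truth).sum()
    auc_a, auc_b = va.mean(), vb.mean()
    d10 = np.cov(np.vstack([va, vb]), ddof=1) if m > 1 else np.zeros((2, 2))
    d01 = np.cov(np.vstack([vh_a, vh_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = d10 / m + d01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        p = 1.0 if abs(diff) < 1e-12 else 0.0
        z = 0.0 if abs(diff) < 1e-12 else np.inf
    else:
        z = diff / np.sqrt(var_diff)
        p = 2.0 * sps.norm.sf(abs(z))
    return {"auc_a": float(auc_a), "auc_b": float(auc_b),
            "auc_difference": float(diff), "z": float(z), "p": float(p)}


def _placement_vectors(scores, truth):
    """Mid-rank placement values of diseased (vs healthy) and healthy (vs
    diseased) subjects for arbitrary (here binary) scores."""
    s_dis = scores[truth]
    s_hea = scores[~truth]
    v_dis = np.array(
        [np.mean((x > s_hea) + 0.5 * (x == s_hea)) for x in s_dis]
    )
    v_hea = np.array(
        [np.mean((s_dis > x) + 0.5 * (s_dis == x)) for x in s_hea]
    )
    return v_dis, v_hea


def paired_tests(
    ratings: pd.DataFrame,
    modality_a,
    modality_b,
    reader,
) -> dict:
    """Compare one reader's calls under two modalities on the same subjects.

    Returns exact McNemar p-values on the discordant pairs (overall and
    within the diseased / healthy strata - the sensitivity and specificity
    comparisons), Fisher's exact p on the 2x2 of modality-A call vs
    modality-B call, and the paired DeLong test on the binary-rating AUCs.
    """
    a = ratings[(ratings.modality == modality_a) & (ratings.reader == reader)]
    b = ratings[(ratings.modality == modality_b) & (ratings.reader == reader)]
    a = a.set_index("subject_id").sort_index()
    b = b.set_index("subject_id").sort_index()
    if not a.index.equals(b.index):
        raise ValueError("modalities must be rated on the same subjects")
    ca = a.call.astype(bool).values
    cb = b.call.astype(bool).values
    truth = a.truth.astype(bool).values

    def mcnemar_stratum(mask):
        bb = int((ca & ~cb & mask).sum())
        cc = int((~ca & cb & mask).sum())
        return _mcnemar_exact(bb, cc)

    fisher_table = [
        [int((ca & cb).sum()), int((ca & ~cb).sum())],
        [int((~ca & cb).sum()), int((~ca & ~cb).sum())],
    ]
    _, fisher_p = sps.fisher_exact(fisher_table)
    return {
        "mcnemar_p": mcnemar_stratum(np.ones_like(truth)),
        "mcnemar_p_diseased": mcnemar_stratum(truth),
        "mcnemar_p_healthy": mcnemar_stratum(~truth),
        "fisher_p": float(fisher_p),
        "delong": _delong_paired(ca, cb, truth),
    }


# ---------------------------------------------------------------------------
# Rating-table construction and simulation
# ---------------------------------------------------------------------------


def ratings_from_calls(truth, calls: dict) -> pd.DataFrame:
    """Tidy rating table from per-reader-per-modality boolean call vectors.

    ``truth`` is a boolean vector over subjects; ``calls`` maps
    (reader, modality) to a same-length boolean vector.
    """
    truth = np.asarray(truth, dtype=bool)
    rows = []
    for (reader, modality), vec in calls.items():
        vec = np.asarray(vec, dtype=bool)
        if len(vec) != len(truth):
            raise ValueError("call vector length mismatch")
        for sid, (t, c) in enumerate(zip(truth, vec)):
            rows.append((sid, int(t), reader, modality, int(c)))
    return pd.DataFrame(rows, columns=RATING_COLUMNS)


def simulate_ratings(
    n_diseased: int,
    n_healthy: int,
    sensitivity: float,
    specificity: float,
    n_readers: int = 2,
    subject_effect: float = 1.0,
    seed: int = 0,
    modality: str = "sim",
) -> pd.DataFrame:
    """Correlated-reader rating generator.

    Each subject carries a latent difficulty u ~ N(0, subject_effect^2);
    reader r calls subject i positive when ``u_i + e_ri > z`` with
    independent unit-normal reader noise and the threshold z chosen so the
    marginal call probability equals ``sensitivity`` (diseased) or
    ``1 - specificity`` (healthy).  Larger ``subject_effect`` yields higher
    inter-reader agreement at fixed marginal accuracy.
    """
    if not (0.0 < sensitivity < 1.0) or not (0.0 < specificity < 1.0):
        raise ValueError("sensitivity/specificity must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    n = n_diseased + n_healthy
    truth = np.zeros(n, dtype=bool)
    truth[:n_diseased] = True
    total_sd = np.sqrt(subject_effect**2 + 1.0)
    z_pos = sps.norm.ppf(1.0 - sensitivity) * total_sd
    z_neg = sps.norm.ppf(specificity) * total_sd
    u = subject_effect * rng.standard_normal(n)
    calls = {}
    for r in range(n_readers):
        e = rng.standard_normal(n)
        thr = np.where(truth, z_pos, z_neg)
        calls[(f"reader{r + 1}", modality)] = (u + e) > thr
    return ratings_from_calls(truth, calls)


def load_ratings_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RATING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ratings CSV lacks columns: {sorted(missing)}")
    return df[RATING_COLUMNS]


def save_ratings_csv(path, ratings: pd.DataFrame) -> None:
    ratings[RATING_COLUMNS].to_csv(path, index=False)
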