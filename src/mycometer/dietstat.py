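"""Diet processing and diet-microbiome statistics.

Covers the residual method for energy adjustment of nutrient intakes, the
intraclass correlation coefficient and the exact paired Wilcoxon test for
questionnaire reproducibility, Spearman + Benjamini-Hochberg association
screens between diet variables and microbiome features, and longitudinal
dynamics comparisons (intra- vs inter-individual Bray-Curtis dissimilarity,
baseline trajectories, fungal-vs-bacterial paired tests).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .profiler import bray_curtis

__all__ = [
    "energy_adjust",
    "icc",
    "wilcoxon_signed_rank",
    "reproducibility_test",
    "association_screen",
    "DynamicsResult",
    "dynamics_analysis",
    "compare_dynamics",
]


def energy_adjust(diet: pd.DataFrame, energy_col: str = "energy_kcal",
                  nutrient_cols=None,
                  id_cols=("subject", "timepoint")) -> pd.DataFrame:
    """Residual-method energy adjustment.

    Each nutrient is regressed (OLS) on total energy across observations; the
    adjusted intake is the residual plus the nutrient's grand mean, removing
    the confounding of absolute caloric intake.  With constant energy the
    slope is set to 0 (adjustment reduces to the identity) with a warning.
    """
    if energy_col not in diet.columns:
        raise ValueError(f"no {energy_col!r} column")
    if len(diet) < 3:
        raise ValueError("need at least 3 observations")
    if nutrient_cols is None:
        nutrient_cols = [c for c in diet.columns
                         if c not in id_cols and c != energy_col
                         and pd.api.types.is_numeric_dtype(diet[c])]
    e = diet[energy_col].to_numpy(dtype=float)
    e_c = e - e.mean()
    var_e = float((e_c ** 2).sum())
    out = diet.copy()
    for c in nutrient_cols:
        y = diet[c].to_numpy(dtype=float)
        if var_e == 0:
            warnings.warn(f"energy is constant; {c} left unadjusted (slope 0)")
            slope = 0.0
        else:
            slope = float((e_c * (y - y.mean())).sum() / var_e)
        fitted = y.mean() + slope * e_c
        out[c] = y - fitted + y.mean()
    return out


def icc(time1, time2, form: str = "absolute") -> float:
    """Intraclass correlation for two administrations per subject.

    ``form='absolute'`` gives the two-way random-effects, absolute-agreement,
    single-measure ICC(2,1); ``form='consistency'`` the consistency ICC(3,1).
    The estimate may be negative.  Zero total variance is an error.
    """
    x = np.asarray(time1, dtype=float)
    y = np.asarray(time2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("time1/time2 must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 subjects")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("zero total variance: ICC undefined")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if form == "absolute":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "consistency":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError("form must be 'absolute' or 'consistency'")
    if denom == 0:
        raise ValueError("zero variance: ICC undefined")
    return float((msr - mse) / denom)


def _signed_rank_stat(d: np.ndarray) -> tuple[float, np.ndarray]:
    ranks = stats.rankdata(np.abs(d))  # midranks for ties
    w_plus = float(ranks[d > 0].sum())
    return w_plus, ranks


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p by dynamic programming over the 2^n sign
    assignments.  Midranks are doubled so all rank sums are integers."""
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:counts.size - r]
        counts = counts + shifted
    w2 = int(round(2 * w_plus))
    lo = min(w2, total - w2)
    hi = max(w2, total - w2)
    p = (counts[:lo + 1].sum() + counts[hi:].sum()) / counts.sum()
    return float(min(p, 1.0))


def wilcoxon_signed_rank(x, y=None, exact_limit: int = 25) -> tuple[float, float, bool]:
    """Paired Wilcoxon signed-rank test: (W+, two-sided p, degenerate flag).

    Zero differences are dropped.  For n <= ``exact_limit`` the p-value comes
    from the exact signed-rank distribution (enumeration by DP, midranks for
    ties); above that, the normal approximation with tie correction and
    continuity correction is used.  All differences zero -> p = 1, flagged.
    """
    d = np.asarray(x, dtype=float) - (0 if y is None else np.asarray(y, dtype=float))
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0, True
    w_plus, ranks = _signed_rank_stat(d)
    if n <= exact_limit:
        return w_plus, _exact_signed_rank_p(w_plus, ranks), False
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts ** 3 - tie_counts).sum() / 48.0
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    return w_plus, float(2 * stats.norm.sf(abs(z))), False


def reproducibility_test(time1: pd.DataFrame, time2: pd.DataFrame) -> pd.DataFrame:
    """Per-variable paired Wilcoxon between two questionnaire administrations
    (rows aligned by subject, columns are variables)."""
    common = [c for c in time1.columns if c in time2.columns]
    if not common:
        raise ValueError("no shared variables")
    rows = []
    for c in common:
        w, p, flag = wilcoxon_signed_rank(time1[c].to_numpy(dtype=float),
                                          time2[c].to_numpy(dtype=float))
        rows.append({"variable": c, "w_plus": w, "p": p, "degenerate": flag})
    return pd.DataFrame(rows).set_index("variable")


def association_screen(features: pd.DataFrame, diet: pd.DataFrame,
                       fdr_max: float = 0.05, min_pairs: int = 4,
                       partial_on: pd.DataFrame | None = None) -> pd.DataFrame:
    """Spearman correlations of every (feature, diet variable) pair with a
    joint Benjamini-Hochberg adjustment over the whole screen.

    Samples are aligned on the index; constant columns are excluded with a
    warning.  ``partial_on`` optionally residualizes both sides (OLS) on the
    given covariates before ranking (partial-correlation mode).
    """
    from statsmodels.stats.multitest import multipletests

    idx = features.index.intersection(diet.index)
    if len(idx) == 0:
        raise ValueError("no overlapping samples")
    F = features.loc[idx].astype(float)
    D = diet.loc[idx].astype(float)

    if partial_on is not None:
        C = partial_on.loc[idx].astype(float).to_numpy()
        C = np.column_stack([np.ones(len(idx)), C])

        def residualize(df: pd.DataFrame) -> pd.DataFrame:
            out = df.copy()
            for c in df.columns:
                beta, *_ = np.linalg.lstsq(C, df[c].to_numpy(), rcond=None)
                out[c] = df[c].to_numpy() - C @ beta
            return out

        F, D = residualize(F), residualize(D)

    dropped = [c for c in F.columns if F[c].nunique() <= 1] + \
              [c for c in D.columns if D[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"constant columns excluded from the screen: {dropped}")
    fcols = [c for c in F.columns if F[c].nunique() > 1]
    dcols = [c for c in D.columns if D[c].nunique() > 1]

    rows = []
    for fc in fcols:
        for dc in dcols:
            pair = pd.concat([F[fc], D[dc]], axis=1).dropna()
            if len(pair) < min_pairs:
                continue
            rho, p = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
            rows.append({"feature": fc, "variable": dc,
                         "rho": float(rho), "p": float(p)})
    if not rows:
        raise ValueError("no testable pairs")
    table = pd.DataFrame(rows)
    table["fdr"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table["significant"] = table["fdr"] < fdr_max
    return table


# ---------------------------------------------------------------------------
# longitudinal dynamics


@dataclass
class DynamicsResult:
    dissimilarities: pd.DataFrame  # columns: subject_a, t_a, subject_b, t_b, value, kind
    baseline: pd.DataFrame         # columns: subject, timepoint, value
    intra_vs_inter: tuple[float, float] | None  # rank-sum (stat, p)
    degenerate: bool = False

    @property
    def intra(self) -> np.ndarray:
        d = self.dissimilarities
        return d.loc[d["kind"] == "intra", "value"].to_numpy()

    @property
    def inter(self) -> np.ndarray:
        d = self.dissimilarities
        return d.loc[d["kind"] == "inter", "value"].to_numpy()


def dynamics_analysis(profiles: pd.DataFrame, metric=bray_curtis) -> DynamicsResult:
    """Pairwise dissimilarities labelled intra-/inter-individual, per-subject
    trajectories against the first timepoint, and an intra-vs-inter rank-sum
    test.

    ``profiles`` is samples x taxa with a (subject, timepoint) MultiIndex.
    Subjects with a single timepoint contribute no intra pairs (warning).
    """
    if not isinstance(profiles.index, pd.MultiIndex):
        try:
            profiles = profiles.set_axis(
                pd.MultiIndex.from_tuples(profiles.index))
        except TypeError:
            raise ValueError("profiles need a (subject, timepoint) MultiIndex")
    if profiles.index.nlevels != 2:
        raise ValueError("profiles need a (subject, timepoint) MultiIndex")
    subjects = profiles.index.get_level_values(0)
    if subjects.nunique() < 2:
        raise ValueError("need at least 2 subjects")
    singles = [s for s, g in profiles.groupby(level=0) if len(g) < 2]
    if singles:
        warnings.warn(f"subjects with a single timepoint excluded from the "
                      f"intra set: {singles}")

    samples = list(profiles.index)
    vectors = {ix: profiles.loc[ix].to_dict() for ix in samples}
    rows = []
    for (a, b) in itertools.combinations(samples, 2):
        val = metric(vectors[a], vectors[b])
        rows.append({"subject_a": a[0], "t_a": a[1], "subject_b": b[0],
                     "t_b": b[1], "value": val,
                     "kind": "intra" if a[0] == b[0] else "inter"})
    diss = pd.DataFrame(rows)

    base_rows = []
    for s, g in profiles.groupby(level=0):
        tps = sorted(g.index.get_level_values(1))
        if len(tps) < 2:
            continue
        t0 = tps[0]
        for t in tps[1:]:
            base_rows.append({"subject": s, "timepoint": t,
                              "value": metric(vectors[(s, t0)], vectors[(s, t)])})
    baseline = pd.DataFrame(base_rows)

    intra = diss.loc[diss["kind"] == "intra", "value"].to_numpy()
    inter = diss.loc[diss["kind"] == "inter", "value"].to_numpy()
    degenerate = False
    test = None
    if intra.size and inter.size:
        if np.ptp(np.concatenate([intra, inter])) == 0:
            degenerate = True
        else:
            u, p = stats.mannwhitneyu(inter, intra, alternative="greater")
            test = (float(u), float(p))
    return DynamicsResult(diss, baseline, test, degenerate)


def compare_dynamics(a: DynamicsResult, b: DynamicsResult) -> tuple[float, float, bool]:
    """Paired Wilcoxon between two communities' baseline dissimilarities,
    matched on (subject, timepoint): e.g. fungal vs bacterial dynamics."""
    merged = a.baseline.merge(b.baseline, on=["subject", "timepoint"],
                              suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("no matched (subject, timepoint) trajectories")
    return wilcoxon_signed_rank(merged["value_a"].to_numpy(),
                                merged["value_b"].to_numpy())
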