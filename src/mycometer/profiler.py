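"""Depth-based taxonomic profiling, diversity metrics and related calculators.

Profiling follows the mapping-depth convention: the relative abundance of a
mapping hit is its end-trimmed mean depth divided by the sum over all hits,
hits below a minimum depth (default 15) are discarded as likely off-target
mappings, hits are aggregated by taxon at the requested rank, and taxa
outside the expected community are pooled into an off-target mass.

Also here: TMM count normalization, alpha diversity (observed / Shannon /
Chao1), Bray-Curtis, weighted UniFrac over a rank-lineage tree, rarefaction,
the fungal-enrichment fold-change, and the Stokes-law sedimentation
calculator used to design the enrichment centrifugation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Hit",
    "AbundanceProfile",
    "depth_profile_to_abundance",
    "tmm_normalize",
    "alpha_diversity",
    "bray_curtis",
    "lineage_tree",
    "weighted_unifrac",
    "rarefaction_curve",
    "enrichment_ratio",
    "SedimentationParams",
    "stokes_solve",
]

OFF_TARGET = "__off_target__"


@dataclass(frozen=True)
class Hit:
    """One reference gene with its trimmed mean depth and taxon labels."""

    gene: str
    depth: float
    species: str
    genus: str | None = None
    kingdom: str = "Fungi"

    def label(self, level: str) -> str:
        if level == "species":
            return self.species
        if level == "genus":
            if self.genus is None:
                raise ValueError(f"hit {self.gene} has no genus label")
            return self.genus
        raise ValueError(f"unknown rank {level!r}")


@dataclass
class AbundanceProfile:
    level: str
    abundances: dict[str, float]
    off_target_mass: float = 0.0

    def __post_init__(self):
        total = sum(self.abundances.values()) + self.off_target_mass
        if self.abundances and abs(total - 1.0) > 1e-9:
            raise ValueError(f"profile sums to {total}, not 1")
        if any(v < 0 for v in self.abundances.values()) or self.off_target_mass < 0:
            raise ValueError("negative abundance")

    def as_dict(self, include_off_target: bool = True) -> dict[str, float]:
        out = dict(self.abundances)
        if include_off_target and self.off_target_mass > 0:
            out[OFF_TARGET] = self.off_target_mass
        return out


def depth_profile_to_abundance(hits: list[Hit], min_depth: float = 15,
                               level: str = "species",
                               expected_taxa=None) -> AbundanceProfile:
    """Depth filter -> per-hit relative abundance -> per-taxon aggregation
    -> off-target pooling."""
    if not hits:
        raise ValueError("no hits")
    surviving = [h for h in hits if h.depth >= min_depth]
    if not surviving:
        raise ValueError(f"all hits below the depth filter ({min_depth})")
    total = sum(h.depth for h in surviving)
    abund: dict[str, float] = {}
    for h in surviving:
        key = h.label(level)
        abund[key] = abund.get(key, 0.0) + h.depth / total
    off = 0.0
    if expected_taxa is not None:
        expected = set(expected_taxa)
        off = sum(v for k, v in abund.items() if k not in expected)
        abund = {k: v for k, v in abund.items() if k in expected}
    return AbundanceProfile(level, abund, off)


# ---------------------------------------------------------------------------
# TMM normalization (trimmed mean of M-values)


def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
                     logratio_trim: float, abs_trim: float) -> float:
    both = (obs > 0) & (ref > 0)
    if not both.any():
        return np.nan
    o = obs[both] / lib_obs
    r = ref[both] / lib_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    w = (lib_obs - obs[both]) / (lib_obs * obs[both]) + \
        (lib_ref - ref[both]) / (lib_ref * ref[both])
    n = m.size
    lo_m = math.floor(n * logratio_trim) + 1
    hi_m = n - math.floor(n * logratio_trim)
    lo_a = math.floor(n * abs_trim) + 1
    hi_a = n - math.floor(n * abs_trim)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    return float(2 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])))


def tmm_normalize(counts: pd.DataFrame, ref_sample: str | None = None,
                  logratio_trim: float = 0.3, abs_trim: float = 0.05
                  ) -> tuple[pd.Series, pd.DataFrame]:
    """TMM scaling factors and effective-library-scaled counts.

    ``counts`` is samples x features.  The reference sample is the one whose
    upper quartile (of counts/library size) is closest to the mean upper
    quartile.  M-values are doubly trimmed (30% on M, 5% on A) and averaged
    with inverse asymptotic-variance weights; factors are rescaled to a
    geometric mean of 1.
    """
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    lib = counts.sum(axis=1).astype(float)
    if (lib <= 0).any():
        raise ValueError("every sample needs a positive total")
    if ref_sample is None:
        f75 = counts.div(lib, axis=0).quantile(0.75, axis=1)
        ref_sample = (f75 - f75.mean()).abs().idxmin()
    ref = counts.loc[ref_sample].to_numpy(dtype=float)
    lib_ref = float(lib.loc[ref_sample])

    factors = {}
    for s in counts.index:
        if s == ref_sample:
            factors[s] = 1.0
            continue
        f = _tmm_pair_factor(counts.loc[s].to_numpy(dtype=float), ref,
                             float(lib.loc[s]), lib_ref, logratio_trim, abs_trim)
        if np.isnan(f):
            warnings.warn(f"sample {s} shares no positive features with the "
                          "reference; factor set to 1")
            f = 1.0
        factors[s] = f
    fac = pd.Series(factors).reindex(counts.index)
    fac /= np.exp(np.log(fac).mean())  # geometric mean 1
    eff = lib * fac
    scaled = counts.div(eff, axis=0) * eff.mean()
    return fac, scaled


# ---------------------------------------------------------------------------
# diversity


def alpha_diversity(x) -> tuple[int, float, float | None]:
    """(observed, Shannon with natural log, Chao1).

    Chao1 = S + f1^2 / (2 f2), with the bias-corrected form
    S + f1 (f1 - 1) / (2 (f2 + 1)) when f2 = 0; it needs integer counts and
    is None for non-integer input (e.g. relative abundances).
    """
    if isinstance(x, AbundanceProfile):
        vals = np.array(list(x.abundances.values()), dtype=float)
    else:
        vals = np.asarray(pd.Series(x).to_numpy(), dtype=float)
    if vals.size == 0 or vals.sum() == 0:
        warnings.warn("empty sample: all alpha metrics 0")
        return 0, 0.0, 0.0
    pos = vals[vals > 0]
    observed = int(pos.size)
    p = pos / pos.sum()
    shannon = float(-(p * np.log(p)).sum())
    chao1: float | None
    if np.allclose(pos, np.round(pos)):
        c = np.round(pos).astype(int)
        f1 = int((c == 1).sum())
        f2 = int((c == 2).sum())
        if f2 > 0:
            chao1 = observed + f1 * f1 / (2.0 * f2)
        else:
            chao1 = observed + f1 * (f1 - 1) / 2.0
    else:
        chao1 = None
    return observed, shannon, chao1


def _common_space(p, q):
    pd_, qd = dict(p), dict(q)
    keys = sorted(set(pd_) | set(qd))
    pv = np.array([pd_.get(k, 0.0) for k in keys])
    qv = np.array([qd.get(k, 0.0) for k in keys])
    return keys, pv, qv


def bray_curtis(p, q) -> float:
    """1 - 2 sum(min) / sum(total) over the union feature space."""
    if isinstance(p, AbundanceProfile):
        p = p.as_dict()
    if isinstance(q, AbundanceProfile):
        q = q.as_dict()
    _, pv, qv = _common_space(p, q)
    tot = pv.sum() + qv.sum()
    if tot == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero profiles")
    return float(1.0 - 2.0 * np.minimum(pv, qv).sum() / tot)


def lineage_tree(lineages: dict[str, tuple], with_off_target: bool = True):
    """Rooted tree from rank lineages (e.g. taxon -> (kingdom, genus)) with
    unit branch lengths; leaves are the taxa.  An off-target leaf hangs
    directly under the root so pooled off-target mass stays in the metric
    without inventing a lineage."""
    from skbio import TreeNode

    root = TreeNode(name="root")
    nodes: dict[tuple, "TreeNode"] = {(): root}
    for taxon, lineage in lineages.items():
        path = ()
        parent = root
        for rank in lineage:
            path = path + (rank,)
            if path not in nodes:
                child = TreeNode(name=str(rank), length=1.0)
                parent.append(child)
                nodes[path] = child
            parent = nodes[path]
        leaf = TreeNode(name=taxon, length=1.0)
        parent.append(leaf)
    if with_off_target:
        root.append(TreeNode(name=OFF_TARGET, length=1.0))
    return root


def weighted_unifrac(p, q, tree, normalized: bool = True) -> float:
    """Weighted UniFrac: sum over branches of l_b |A_b - B_b| where A_b, B_b
    are the abundance fractions descending branch b; divided by
    sum l_b (A_b + B_b) when normalized."""
    if isinstance(p, AbundanceProfile):
        p = p.as_dict()
    if isinstance(q, AbundanceProfile):
        q = q.as_dict()
    leaves = {n.name for n in tree.tips()}
    missing = (set(p) | set(q)) - leaves
    if missing:
        raise ValueError(f"taxa absent from tree: {sorted(missing)}")
    ptot = sum(p.values()) or 1.0
    qtot = sum(q.values()) or 1.0

    raw = 0.0
    denom = 0.0
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            node._wu_a = p.get(node.name, 0.0) / ptot
            node._wu_b = q.get(node.name, 0.0) / qtot
        else:
            node._wu_a = sum(c._wu_a for c in node.children)
            node._wu_b = sum(c._wu_b for c in node.children)
        l = node.length if node.length is not None else 1.0
        raw += l * abs(node._wu_a - node._wu_b)
        denom += l * (node._wu_a + node._wu_b)
    if normalized:
        return float(raw / denom) if denom > 0 else 0.0
    return float(raw)


def rarefaction_curve(counts, depth_grid, n_reps: int = 10, seed: int = 0) -> pd.DataFrame:
    """Mean richness (as % of full-depth richness) from subsampling reads
    without replacement at each depth of the grid."""
    c = np.asarray(pd.Series(counts).to_numpy(), dtype=np.int64)
    total = int(c.sum())
    full_richness = int((c > 0).sum())
    rng = np.random.default_rng(seed)
    rows = []
    for d in depth_grid:
        if d > total:
            raise ValueError(f"subsampling depth {d} exceeds total reads {total}")
        rich = []
        for _ in range(n_reps):
            sub = rng.multivariate_hypergeometric(c, int(d))
            rich.append(int((sub > 0).sum()))
        rows.append({"depth": int(d), "mean_richness": float(np.mean(rich)),
                     "richness_pct": 100.0 * np.mean(rich) / full_richness})
    return pd.DataFrame(rows)


def enrichment_ratio(fungal_enriched, bacterial_enriched,
                     fungal_control, bacterial_control) -> pd.DataFrame:
    """Per-sample fungal/bacterial read ratio per partition and the
    enrichment fold change (enriched-partition ratio / control ratio).

    All four inputs are aligned per-sample arrays of mapped-read counts.
    """
    fe = np.asarray(fungal_enriched, dtype=float)
    be = np.asarray(bacterial_enriched, dtype=float)
    fc = np.asarray(fungal_control, dtype=float)
    bc = np.asarray(bacterial_control, dtype=float)
    if (be <= 0).any() or (bc <= 0).any():
        raise ValueError("bacterial mapped reads must be positive in both partitions")
    ratio_e = fe / be
    ratio_c = fc / bc
    fold = np.where(ratio_c > 0, ratio_e / np.where(ratio_c > 0, ratio_c, 1.0), np.nan)
    if np.isnan(fold).any():
        warnings.warn("control partitions with zero fungal/bacterial ratio: "
                      "fold undefined (NaN) for those samples")
    return pd.DataFrame({"ratio_enriched": ratio_e, "ratio_control": ratio_c,
                         "fold": fold})


# ---------------------------------------------------------------------------
# Stokes-law sedimentation calculator


@dataclass
class SedimentationParams:
    """D (cm), eta (poise), Rf/Ro (cm), rho_p/rho_f (g/ml), omega (rad/s),
    t (s).  Set exactly one of D, omega, t to None to solve for it."""

    eta: float
    Rf: float
    Ro: float
    rho_p: float
    rho_f: float
    D: float | None = None
    omega: float | None = None
    t: float | None = None

    def validate(self) -> str:
        unknowns = [n for n in ("D", "omega", "t") if getattr(self, n) is None]
        if len(unknowns) != 1:
            raise ValueError("exactly one of D, omega, t must be unknown (None)")
        for n in ("eta", "Rf", "Ro"):
            if getattr(self, n) <= 0:
                raise ValueError(f"{n} must be positive")
        if self.Rf <= self.Ro:
            raise ValueError("Rf must exceed Ro")
        for n in ("D", "omega", "t"):
            v = getattr(self, n)
            if v is not None and v <= 0:
                raise ValueError(f"{n} must be positive")
        return unknowns[0]


def stokes_solve(params: SedimentationParams) -> float:
    """Solve D = (18 eta ln(Rf/Ro) / ((rho_p - rho_f) omega^2 t))^0.5 for the
    one unknown among D, omega, t."""
    unknown = params.validate()
    drho = params.rho_p - params.rho_f
    if drho <= 0:
        raise ValueError("rho_p must exceed rho_f: the particle does not sediment")
    num = 18.0 * params.eta * math.log(params.Rf / params.Ro)
    if unknown == "D":
        return math.sqrt(num / (drho * params.omega ** 2 * params.t))
    if unknown == "t":
        return num / (drho * params.omega ** 2 * params.D ** 2)
    return math.sqrt(num / (drho * params.t * params.D ** 2))
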