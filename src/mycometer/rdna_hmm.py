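"""CN-HMM: ITS copy number from genome assemblies.

The internal transcribed spacer (ITS) sits between the large- and
small-subunit rRNA genes in the rDNA tandem array.  The conserved edges of
those genes (the "LSU" and "SSU" flanks) anchor ITS detection: a profile HMM
is trained on an alignment of each flank, both strands of the assembly are
scanned, hits are filtered at an E-value cutoff (default 0.001), and LSU/SSU
hits are paired into ITS loci whenever the inner-edge gap — the ITS length —
lies in [400, 800] bp (fungal ITS lengths average 550 bp).  A hit whose
partner window runs off the contig end still counts as one (end-truncated)
copy, because collapsed assemblies frequently break inside the array.

The copy number of a genome is the number of loci so found.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._viterbi import scan_kernel
from .simkit import GenomeAssembly, encode, revcomp

__all__ = [
    "ProfileHMM",
    "HmmHit",
    "PairingParams",
    "ITSLocus",
    "CNHMMResult",
    "build_profile",
    "scan_sequence",
    "count_copies",
    "extract_its",
    "cn_hmm_pipeline",
]

_GAPS = set("-.~")


def _read_alignment(alignment):
    """Accept a list of (name, row) pairs, a list of rows, or a path to an
    aligned FASTA / Stockholm file."""
    import os

    if isinstance(alignment, (str, os.PathLike)) or hasattr(alignment, "read"):
        from Bio import AlignIO

        fmt = "stockholm" if str(alignment).endswith((".sto", ".stk", ".stockholm")) else "fasta"
        aln = AlignIO.read(str(alignment), fmt)
        return [(rec.id, str(rec.seq)) for rec in aln]
    rows = []
    for item in alignment:
        if isinstance(item, str):
            rows.append((f"seq_{len(rows)}", item))
        else:
            rows.append((item[0], item[1]))
    return rows


@dataclass
class ProfileHMM:
    """Position-specific model of an rDNA flank.

    ``match_emissions`` has one row per match state (M x 4, A/C/G/T order);
    transition arrays have length M-1 and hold log2 probabilities from
    position j to j+1.  ``k_ev`` is the Gumbel scale constant fitted by
    :meth:`calibrate`; the decay rate is fixed at lambda = ln 2, i.e.
    E(S) = k_ev * (scanned residues) * 2**(-S).
    """

    name: str
    match_emissions: np.ndarray
    background: np.ndarray
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    k_ev: float | None = None
    _mllr: np.ndarray = field(default=None, repr=False)

    @property
    def M(self) -> int:
        return self.match_emissions.shape[0]

    @property
    def consensus_codes(self) -> np.ndarray:
        return np.argmax(self.match_emissions, axis=1)

    @property
    def match_llr(self) -> np.ndarray:
        """(M, 5) log2-odds table; column 4 (ambiguous base) scores 0."""
        if self._mllr is None:
            llr = np.zeros((self.M, 5))
            llr[:, :4] = np.log2(self.match_emissions / self.background[None, :])
            self._mllr = llr
        return self._mllr

    def _kernel_args(self):
        lg = lambda a: np.log2(a)
        return (self.match_llr, lg(self.t_mm), lg(self.t_mi), lg(self.t_md),
                lg(self.t_im), lg(self.t_ii), lg(self.t_dm), lg(self.t_dd),
                math.log2(1.0 / self.M))

    def score_ends(self, seq_codes: np.ndarray):
        """Best local-alignment score ending at each position, plus the start
        of that alignment."""
        if self.M < 1:
            raise ValueError("empty profile")
        return scan_kernel(seq_codes.astype(np.int64), *self._kernel_args())

    def calibrate(self, reference: str | None = None, seed: int = 0,
                  length: int = 60_000, top_n: int = 20) -> float:
        """Fit the E-value constant K on dinucleotide-matched random sequence.

        A first-order Markov chain estimated from ``reference`` (uniform if
        None) generates a decoy sequence of ``length`` bp; non-overlapping
        local hits are collected and the Gumbel tail with fixed lambda = ln 2
        is anchored at the ``top_n``-th best score:  K = n * 2**s_n / L.
        """
        rng = np.random.default_rng(seed)
        if reference:
            codes = encode(reference)
            codes = codes[codes < 4]
            trans = np.ones((4, 4))
            np.add.at(trans, (codes[:-1], codes[1:]), 1)
            trans /= trans.sum(axis=1, keepdims=True)
            decoy = np.empty(length, dtype=np.int64)
            decoy[0] = rng.integers(0, 4)
            u = rng.random(length)
            cum = np.cumsum(trans, axis=1)
            for i in range(1, length):
                decoy[i] = np.searchsorted(cum[decoy[i - 1]], u[i])
        else:
            decoy = rng.integers(0, 4, size=length)
        scores, starts = self.score_ends(decoy)
        hits = _greedy_hits(scores, starts, length, min_score=0.0)
        hits.sort(key=lambda h: -h[2])
        hits = hits[:top_n]
        if not hits:
            self.k_ev = 1.0 / length
            return self.k_ev
        n = len(hits)
        s_n = hits[-1][2]
        self.k_ev = n * 2.0 ** s_n / length
        return self.k_ev


def build_profile(alignment, name: str = "flank", gap_threshold: float = 0.5) -> ProfileHMM:
    """Train a flank profile from a multiple alignment.

    Columns with a gap fraction below ``gap_threshold`` become match states;
    emissions are (count + 1) / (total + 4) with the +1 Laplace pseudocount,
    and state transitions get the same +1 pseudocount over their outgoing
    options.  Background is uniform.
    """
    rows = _read_alignment(alignment)
    if len(rows) < 2:
        raise ValueError("alignment must contain at least 2 sequences")
    L = len(rows[0][1])
    if any(len(r[1]) != L for r in rows):
        raise ValueError("ragged alignment: sequences have unequal aligned lengths")

    mat = np.array([list(r[1].upper()) for r in rows])
    n_seqs = len(rows)
    is_gap = np.isin(mat, list(_GAPS))
    gap_frac = is_gap.mean(axis=0)
    match_cols = np.where(gap_frac < gap_threshold)[0]
    M = len(match_cols)
    if M < 1:
        raise ValueError("no match columns in alignment")

    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
    emis = np.ones((M, 4))  # +1 pseudocount
    for mi, col in enumerate(match_cols):
        for ch in mat[:, col]:
            if ch in base_idx:
                emis[mi, base_idx[ch]] += 1
    emis /= emis.sum(axis=1, keepdims=True)

    # transition counts between consecutive match columns, +1 pseudocounts
    c_mm = np.ones(max(M - 1, 0)); c_mi = np.ones(max(M - 1, 0)); c_md = np.ones(max(M - 1, 0))
    c_im = np.ones(max(M - 1, 0)); c_ii = np.ones(max(M - 1, 0))
    c_dm = np.ones(max(M - 1, 0)); c_dd = np.ones(max(M - 1, 0))
    for _, row in rows:
        states = ["D" if row[c].upper() in _GAPS or row[c] in _GAPS else "M"
                  for c in match_cols]
        for j in range(M - 1):
            lo, hi = match_cols[j] + 1, match_cols[j + 1]
            n_ins = sum(1 for c in range(lo, hi)
                        if row[c].upper() in base_idx)
            a, b = states[j], states[j + 1]
            if n_ins > 0 and a == "M" and b == "M":
                c_mi[j] += 1
                c_ii[j] += n_ins - 1
                c_im[j] += 1
            else:
                if a == "M" and b == "M":
                    c_mm[j] += 1
                elif a == "M" and b == "D":
                    c_md[j] += 1
                elif a == "D" and b == "M":
                    c_dm[j] += 1
                elif a == "D" and b == "D":
                    c_dd[j] += 1
    m_tot = c_mm + c_mi + c_md
    i_tot = c_im + c_ii
    d_tot = c_dm + c_dd
    return ProfileHMM(
        name=name,
        match_emissions=emis,
        background=np.full(4, 0.25),
        t_mm=c_mm / m_tot, t_mi=c_mi / m_tot, t_md=c_md / m_tot,
        t_im=c_im / i_tot, t_ii=c_ii / i_tot,
        t_dm=c_dm / d_tot, t_dd=c_dd / d_tot,
    )


@dataclass(frozen=True)
class HmmHit:
    contig: str
    start: int
    end: int
    strand: str
    score: float
    e_value: float

    def overlaps(self, other: "HmmHit") -> bool:
        return self.contig == other.contig and self.start < other.end and other.start < self.end


def _greedy_hits(scores: np.ndarray, starts: np.ndarray, seq_len: int,
                 min_score: float) -> list[tuple[int, int, float]]:
    """Greedy non-overlapping interval selection by score.

    Returns (start, end, score) triples with end = position + 1 (half-open).
    """
    cand = np.where(scores >= min_score)[0]
    if cand.size == 0:
        return []
    order = cand[np.argsort(scores[cand])[::-1]]
    occupied = np.zeros(seq_len, dtype=bool)
    out = []
    for i in order:
        s, e = int(starts[i]), int(i) + 1
        if s >= e:
            continue
        if occupied[s:e].any():
            continue
        occupied[s:e] = True
        out.append((s, e, float(scores[i])))
    return out


def _seed_windows(profile: ProfileHMM, codes: np.ndarray, seed_k: int = 16,
                  margin: int = 30) -> list[tuple[int, int]]:
    """Candidate windows for the full Viterbi: positions where a ``seed_k``-mer
    of the profile consensus occurs exactly anchor an alignment start, and a
    window of the profile length (plus ``margin`` slack for indels) around
    each anchor is scanned.  This is the standard accelerator heuristic of
    profile search tools; at the divergences rDNA flanks show, a true flank
    contains many exact consensus words, while random sequence contains
    almost none."""
    M = profile.M
    n = codes.size
    if M < seed_k or n < seed_k:
        return [(0, n)] if n else []
    cons = profile.consensus_codes.astype(np.int64)
    pow4 = 4 ** np.arange(seed_k - 1, -1, -1, dtype=np.int64)
    cons_win = np.lib.stride_tricks.sliding_window_view(cons, seed_k)
    offsets: dict[int, list[int]] = {}
    for o, key in enumerate(cons_win @ pow4):
        offsets.setdefault(int(key), []).append(o)
    twin = np.lib.stride_tricks.sliding_window_view(codes, seed_k)
    valid = (twin < 4).all(axis=1)
    keys = twin @ pow4
    anchor_starts: set[int] = set()
    for p in np.where(valid)[0]:
        hit = offsets.get(int(keys[p]))
        if hit:
            for o in hit:
                anchor_starts.add(int(p) - o)
    if not anchor_starts:
        return []
    windows = sorted((max(0, a - margin), min(n, a + M + margin))
                     for a in anchor_starts)
    merged = [list(windows[0])]
    for (s, e) in windows[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def scan_sequence(profile: ProfileHMM, assembly, e_max: float = 0.001,
                  prefilter: bool = True) -> list[HmmHit]:
    """Scan both strands of an assembly, returning E-filtered, per-strand
    non-overlapping hits with forward-strand coordinates.

    With ``prefilter`` (default) the Viterbi runs only inside consensus-seeded
    candidate windows; set False to force the full dynamic program everywhere.
    """
    if profile.M < 1:
        raise ValueError("empty profile")
    contigs = assembly.contigs if isinstance(assembly, GenomeAssembly) else dict(assembly)
    if not contigs or all(len(s) == 0 for s in contigs.values()):
        raise ValueError("assembly is empty")

    if profile.k_ev is None:
        ref = max(contigs.values(), key=len)
        profile.calibrate(reference=ref)

    db_len = 2 * sum(len(s) for s in contigs.values())
    s_min = math.log2(profile.k_ev * db_len / e_max)

    hits: list[HmmHit] = []
    for cname, seq in contigs.items():
        L = len(seq)
        if L == 0:
            continue
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            codes = encode(s)
            windows = _seed_windows(profile, codes) if prefilter else [(0, L)]
            cand: list[tuple[int, int, float]] = []
            for (ws, we) in windows:
                scores, starts = profile.score_ends(codes[ws:we])
                ok = np.where(scores >= s_min)[0]
                for i in ok:
                    cand.append((ws + int(starts[i]), ws + int(i) + 1,
                                 float(scores[i])))
            # greedy non-overlap per strand across the whole contig
            occupied = np.zeros(L, dtype=bool)
            for (st, en, sc) in sorted(cand, key=lambda c: -c[2]):
                if st >= en or occupied[st:en].any():
                    continue
                occupied[st:en] = True
                fst, fen = (st, en) if strand == "+" else (L - en, L - st)
                ev = profile.k_ev * db_len * 2.0 ** (-sc)
                hits.append(HmmHit(cname, fst, fen, strand, sc, ev))
    hits.sort(key=lambda h: (h.contig, h.start))
    return hits


@dataclass(frozen=True)
class PairingParams:
    min_gap: int = 400
    max_gap: int = 800
    e_max: float = 0.001
    end_window: int | None = None  # defaults to max_gap

    def __post_init__(self):
        if not 0 < self.min_gap < self.max_gap:
            raise ValueError("require 0 < min_gap < max_gap")

    @property
    def window(self) -> int:
        return self.max_gap if self.end_window is None else self.end_window


@dataclass(frozen=True)
class ITSLocus:
    contig: str
    start: int
    end: int
    strand: str
    completeness: str  # "paired" | "end_truncated"


@dataclass
class CNHMMResult:
    genome: str
    copy_number: int
    loci: list[ITSLocus]

    def to_json_dict(self) -> dict:
        return {
            "genome": self.genome,
            "copy_number": self.copy_number,
            "loci": [vars(l) for l in self.loci],
        }


def count_copies(lsu_hits: list[HmmHit], ssu_hits: list[HmmHit],
                 contig_lengths: dict[str, int],
                 params: PairingParams = PairingParams(),
                 genome: str = "genome") -> CNHMMResult:
    """Pair LSU/SSU hits into ITS loci and count copies.

    Greedy left-to-right (in the reading direction of the locus strand):
    each LSU hit takes the nearest downstream same-strand SSU hit whose
    inner-edge gap lies in [min_gap, max_gap]; equidistant ties go to the
    higher bit score; each hit is used at most once.  An unpaired hit counts
    as one end-truncated copy iff the window where its partner would sit runs
    past the contig boundary (within ``end_window`` of the appropriate end).
    Overlapping LSU/SSU hit intervals are both discarded with a warning.
    """
    lsu_hits = list(lsu_hits)
    ssu_hits = list(ssu_hits)

    drop_l, drop_s = set(), set()
    for li, lh in enumerate(lsu_hits):
        for si, sh in enumerate(ssu_hits):
            if lh.overlaps(sh):
                drop_l.add(li)
                drop_s.add(si)
    if drop_l:
        warnings.warn(f"{genome}: discarding {len(drop_l)} LSU / {len(drop_s)} SSU "
                      "overlapping hits")
    lsu_hits = [h for i, h in enumerate(lsu_hits) if i not in drop_l]
    ssu_hits = [h for i, h in enumerate(ssu_hits) if i not in drop_s]

    loci: list[ITSLocus] = []
    used_ssu: set[int] = set()
    unpaired_lsu: list[HmmHit] = []

    for contig in sorted({h.contig for h in lsu_hits} | {h.contig for h in ssu_hits}):
        clen = contig_lengths[contig]
        for strand in "+-":
            ls = [h for h in lsu_hits if h.contig == contig and h.strand == strand]
            ss = [(i, h) for i, h in enumerate(ssu_hits)
                  if h.contig == contig and h.strand == strand]
            # reading order along the locus strand
            ls.sort(key=lambda h: h.start, reverse=(strand == "-"))
            for lh in ls:
                best = None
                for si, sh in ss:
                    if si in used_ssu:
                        continue
                    gap = (sh.start - lh.end) if strand == "+" else (lh.start - sh.end)
                    if params.min_gap <= gap <= params.max_gap:
                        key = (gap, -sh.score)
                        if best is None or key < best[0]:
                            best = (key, si, sh, gap)
                if best is not None:
                    _, si, sh, gap = best
                    used_ssu.add(si)
                    if strand == "+":
                        loci.append(ITSLocus(contig, lh.end, sh.start, "+", "paired"))
                    else:
                        loci.append(ITSLocus(contig, sh.end, lh.start, "-", "paired"))
                else:
                    unpaired_lsu.append(lh)
            # unpaired SSU hits on this contig/strand
            for si, sh in ss:
                if si in used_ssu:
                    continue
                w = params.window
                if strand == "+" and sh.start <= w:
                    loci.append(ITSLocus(contig, max(0, sh.start - params.max_gap),
                                         sh.start, "+", "end_truncated"))
                    used_ssu.add(si)
                elif strand == "-" and clen - sh.end <= w:
                    loci.append(ITSLocus(contig, sh.end,
                                         min(clen, sh.end + params.max_gap),
                                         "-", "end_truncated"))
                    used_ssu.add(si)

    for lh in unpaired_lsu:
        clen = contig_lengths[lh.contig]
        w = params.window
        if lh.strand == "+" and clen - lh.end <= w:
            loci.append(ITSLocus(lh.contig, lh.end, min(clen, lh.end + params.max_gap),
                                 "+", "end_truncated"))
        elif lh.strand == "-" and lh.start <= w:
            loci.append(ITSLocus(lh.contig, max(0, lh.start - params.max_gap),
                                 lh.start, "-", "end_truncated"))

    loci.sort(key=lambda l: (l.contig, l.start))
    return CNHMMResult(genome=genome, copy_number=len(loci), loci=loci)


def extract_its(result: CNHMMResult, assembly) -> tuple[list[tuple[str, str]], list[str]]:
    """Extract ITS sequences (paired loci only) and BED rows (all loci).

    Minus-strand loci are reverse-complemented.  Returns (fasta_records,
    bed_rows) where fasta_records are (id, sequence) pairs.
    """
    contigs = assembly.contigs if isinstance(assembly, GenomeAssembly) else dict(assembly)
    records: list[tuple[str, str]] = []
    bed: list[str] = []
    n_skipped = 0
    for i, loc in enumerate(result.loci):
        if loc.contig not in contigs:
            raise ValueError(f"locus contig {loc.contig} not in assembly")
        seq = contigs[loc.contig]
        if loc.start < 0 or loc.end > len(seq):
            raise ValueError(f"locus [{loc.start}, {loc.end}) outside contig {loc.contig}")
        bed.append(f"{loc.contig}\t{loc.start}\t{loc.end}\t"
                   f"ITS_{i:03d}|{loc.completeness}\t0\t{loc.strand}")
        if loc.completeness != "paired":
            n_skipped += 1
            continue
        s = seq[loc.start:loc.end]
        if loc.strand == "-":
            s = revcomp(s)
        records.append((f"{result.genome}|ITS_{i:03d}", s))
    if n_skipped:
        warnings.warn(f"{result.genome}: {n_skipped} end-truncated loci excluded from FASTA")
    return records, bed


def read_bed(path) -> list[ITSLocus]:
    loci = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            c, s, e, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            loci.append(ITSLocus(c, int(s), int(e), strand, name.split("|")[-1]))
    return loci


def cn_hmm_pipeline(assembly, lsu_profile: ProfileHMM, ssu_profile: ProfileHMM,
                    params: PairingParams = PairingParams(),
                    genome: str = "genome") -> CNHMMResult:
    """Scan + pair in one call."""
    lsu_hits = scan_sequence(lsu_profile, assembly, params.e_max)
    ssu_hits = scan_sequence(ssu_profile, assembly, params.e_max)
    contigs = assembly.contigs if isinstance(assembly, GenomeAssembly) else dict(assembly)
    lengths = {c: len(s) for c, s in contigs.items()}
    return count_copies(lsu_hits, ssu_hits, lengths, params, genome=genome)
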