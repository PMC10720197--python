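"""Synthetic inputs for the mycobiome toolkit.

Everything downstream of this module (ITS copy-number estimation, mock-community
profiling, co-abundance networks, diet statistics) is exercised on data built
here: genome assemblies carrying tandem rDNA arrays with a known copy number,
shotgun and copy-number-weighted ITS amplicon read sets, compositional count
matrices with a controlled basis correlation structure, and longitudinal diet
tables.  All generators are deterministic for a given seed and write plain-text
formats (FASTA/FASTQ/TSV/BED/JSON) only.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpecError",
    "ArraySpec",
    "SyntheticGenomeSpec",
    "GenomeAssembly",
    "Locus",
    "GroundTruth",
    "ReadSimParams",
    "Read",
    "ReadSet",
    "Member",
    "CommunitySpec",
    "CompositionalSim",
    "synthesize_genome",
    "flank_training_alignment",
    "simulate_shotgun_reads",
    "simulate_its_amplicons",
    "simulate_compositional_counts",
    "simulate_diet_profiles",
    "random_seq",
    "mutate",
    "revcomp",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i


class SpecError(ValueError):
    """Raised when a synthetic-data specification is inconsistent."""


# ---------------------------------------------------------------------------
# sequence helpers


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A=0 C=1 G=2 T=3, anything else 4)."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _BASES[np.asarray(codes, dtype=np.uint8)].tobytes().decode()


def random_seq(rng: np.random.Generator, n: int) -> str:
    return decode(rng.integers(0, 4, size=n))


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability ``rate``.

    Substitutions always change the base (shift by 1-3 in A/C/G/T space), so a
    rate of r yields an expected Hamming divergence of exactly r.
    """
    if rate <= 0:
        return seq
    codes = encode(seq).astype(np.int64)
    mask = rng.random(codes.size) < rate
    shift = rng.integers(1, 4, size=codes.size)
    codes[mask] = (codes[mask] + shift[mask]) % 4
    return decode(codes)


_RC = str.maketrans("ACGTacgtN", "TGCAtgcaN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# genome synthesis


@dataclass(frozen=True)
class ArraySpec:
    """One tandem rDNA array: ``copy_number`` repeats of LSU-flank / ITS /
    SSU-flank, consecutive copies separated by ``spacer_length`` bp of
    intergenic sequence."""

    contig: int = 0
    start: int = 1000
    copy_number: int = 1
    spacer_length: int = 2000


@dataclass
class SyntheticGenomeSpec:
    """Blueprint of an assembly with planted rDNA arrays and marker genes.

    Defaults mirror the organisms the toolkit targets: flank templates of
    588 bp (LSU side) and 142 bp (SSU side), a 550 bp ITS, and a handful of
    single-copy marker genes per genome.
    """

    contig_lengths: Sequence[int] = (50_000,)
    arrays: Sequence[ArraySpec] = (ArraySpec(),)
    flank_templates: tuple[str, str] | None = None  # (LSU, SSU); None -> random
    its_length: int = 550
    flank_divergence: float = 0.0
    truncate_last_copy: bool = False
    marker_genes: tuple[int, int] = (10, 1000)  # (count, length)
    indel_rate: float = 0.0
    seed: int = 0

    lsu_length: int = 588
    ssu_length: int = 142

    def validate(self) -> None:
        if not 400 <= self.its_length <= 800:
            raise SpecError(f"its_length {self.its_length} outside [400, 800]")
        if not 0 <= self.flank_divergence < 1:
            raise SpecError("flank_divergence must be in [0, 1)")
        for arr in self.arrays:
            if arr.copy_number < 0:
                raise SpecError("copy_number must be >= 0")
            if not 0 <= arr.contig < len(self.contig_lengths):
                raise SpecError(f"array contig {arr.contig} out of range")


@dataclass
class GenomeAssembly:
    name: str
    contigs: dict[str, str]

    def write_fasta(self, path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [SeqRecord(Seq(s), id=c, description="") for c, s in self.contigs.items()]
        SeqIO.write(records, str(path), "fasta")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass(frozen=True)
class Locus:
    """A planted ITS locus.  ``start``/``end`` delimit the ITS itself (between
    the inner edges of the two flanks); flank coordinates are kept alongside."""

    contig: str
    start: int
    end: int
    strand: str = "+"
    flag: str = "paired"  # "paired" | "end_truncated"
    lsu: tuple[int, int] | None = None
    ssu: tuple[int, int] | None = None


@dataclass
class GroundTruth:
    genome: str
    true_copy_number: int
    loci: list[Locus]
    marker_loci: list[tuple[str, int, int, str]]  # (contig, start, end, gene id)
    its_sequence: str
    flank_templates: tuple[str, str]

    def to_json(self, path) -> None:
        payload = {
            "genome": self.genome,
            "true_copy_number": self.true_copy_number,
            "loci": [
                {"contig": l.contig, "start": l.start, "end": l.end,
                 "strand": l.strand, "flag": l.flag}
                for l in self.loci
            ],
            "marker_loci": [list(m) for m in self.marker_loci],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=int)

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for l in self.loci:
                fh.write(f"{l.contig}\t{l.start}\t{l.end}\tITS|{l.flag}\t0\t{l.strand}\n")


def _array_unit_length(spec: SyntheticGenomeSpec) -> int:
    return spec.lsu_length + spec.its_length + spec.ssu_length


def synthesize_genome(spec: SyntheticGenomeSpec, name: str = "genome") -> tuple[GenomeAssembly, GroundTruth]:
    """Build an assembly with planted tandem rDNA arrays and marker genes.

    Each array copy is LSU-flank / ITS / SSU-flank; the two flanks receive
    independent per-copy substitutions at ``flank_divergence`` while the ITS
    is identical across copies (it is the same locus repeated).  With
    ``truncate_last_copy`` the final copy of the last array is placed so that
    its SSU flank would overrun the contig end: the contig is cut at the ITS
    end and the locus is flagged ``end_truncated``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    if spec.flank_templates is None:
        lsu_t = random_seq(rng, spec.lsu_length)
        ssu_t = random_seq(rng, spec.ssu_length)
    else:
        lsu_t, ssu_t = spec.flank_templates
    its_seq = random_seq(rng, spec.its_length)

    contigs = [random_seq(rng, L) for L in spec.contig_lengths]
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(contigs))}
    loci: list[Locus] = []
    truncate_at: dict[int, int] = {}

    def claim(ci: int, s: int, e: int, what: str) -> None:
        if s < 0 or e > len(contigs[ci]):
            raise SpecError(f"{what} [{s}, {e}) outside contig {ci}")
        for (os_, oe) in occupied[ci]:
            if s < oe and os_ < e:
                raise SpecError(f"{what} [{s}, {e}) overlaps existing feature [{os_}, {oe})")
        occupied[ci].append((s, e))

    unit = _array_unit_length(spec)
    n_arrays = len(spec.arrays)
    for ai, arr in enumerate(spec.arrays):
        if arr.copy_number == 0:
            continue
        ci = arr.contig
        is_last_array = ai == n_arrays - 1
        pos = arr.start
        pieces: list[str] = []
        for copy in range(arr.copy_number):
            truncated = (
                spec.truncate_last_copy and is_last_array and copy == arr.copy_number - 1
            )
            lsu = mutate(lsu_t, spec.flank_divergence, rng)
            ssu = mutate(ssu_t, spec.flank_divergence, rng)
            lsu_iv = (pos, pos + len(lsu))
            its_iv = (lsu_iv[1], lsu_iv[1] + spec.its_length)
            if truncated:
                claim(ci, pos, its_iv[1], f"array {ai} copy {copy}")
                pieces.append(lsu + its_seq)
                loci.append(Locus(f"contig_{ci}", its_iv[0], its_iv[1], "+",
                                  "end_truncated", lsu_iv, None))
                truncate_at[ci] = its_iv[1]
                pos = its_iv[1]
            else:
                ssu_iv = (its_iv[1], its_iv[1] + len(ssu))
                end = ssu_iv[1]
                last_of_array = copy == arr.copy_number - 1
                span_end = end if last_of_array else end + arr.spacer_length
                claim(ci, pos, span_end, f"array {ai} copy {copy}")
                spacer = "" if last_of_array else random_seq(rng, arr.spacer_length)
                pieces.append(lsu + its_seq + ssu + spacer)
                loci.append(Locus(f"contig_{ci}", its_iv[0], its_iv[1], "+",
                                  "paired", lsu_iv, ssu_iv))
                pos = span_end
        block = "".join(pieces)
        contigs[ci] = contigs[ci][: arr.start] + block + contigs[ci][arr.start + len(block):]

    # single-copy marker genes, placed uniformly over the remaining free space
    n_markers, marker_len = spec.marker_genes
    marker_loci: list[tuple[str, int, int, str]] = []
    for mi in range(n_markers):
        free: list[tuple[int, int, int]] = []  # (contig, start, end) gaps
        for ci in range(len(contigs)):
            limit = truncate_at.get(ci, len(contigs[ci]))
            edges = sorted(occupied[ci])
            prev = 0
            for (s, e) in edges + [(limit, limit)]:
                if s - prev >= marker_len:
                    free.append((ci, prev, s))
                prev = max(prev, e)
        if not free:
            raise SpecError(f"could not place marker gene {mi}: genome too crowded")
        room = np.array([e - s - marker_len + 1 for _, s, e in free], dtype=float)
        gi = int(rng.choice(len(free), p=room / room.sum()))
        ci, gs, _ge = free[gi]
        s = gs + int(rng.integers(0, int(room[gi])))
        claim(ci, s, s + marker_len, f"marker {mi}")
        gene = random_seq(rng, marker_len)
        contigs[ci] = contigs[ci][:s] + gene + contigs[ci][s + marker_len:]
        marker_loci.append((f"contig_{ci}", s, s + marker_len, f"marker_{mi:03d}"))

    for ci, cut in truncate_at.items():
        contigs[ci] = contigs[ci][:cut]

    assembly = GenomeAssembly(name, {f"contig_{i}": s for i, s in enumerate(contigs)})
    truth = GroundTruth(
        genome=name,
        true_copy_number=len(loci),
        loci=loci,
        marker_loci=marker_loci,
        its_sequence=its_seq,
        flank_templates=(lsu_t, ssu_t),
    )
    return assembly, truth


def flank_training_alignment(template: str, n_seqs: int = 10, divergence: float = 0.02,
                             seed: int = 0) -> list[tuple[str, str]]:
    """Gap-free alignment of diverged copies of ``template`` (name, row) pairs,
    used to train a flank profile HMM the way a curated rRNA alignment would."""
    rng = np.random.default_rng(seed)
    return [(f"seq_{i:02d}", mutate(template, divergence, rng)) for i in range(n_seqs)]


# ---------------------------------------------------------------------------
# read simulation


@dataclass(frozen=True)
class ReadSimParams:
    n_reads: int = 10_000
    read_length: int = 100
    substitution_error_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_reads < 0:
            raise SpecError("n_reads must be >= 0")
        if not 0 <= self.substitution_error_rate < 1:
            raise SpecError("substitution_error_rate must be in [0, 1)")


@dataclass(frozen=True)
class Read:
    name: str
    seq: str

    @property
    def qual(self) -> str:
        return "I" * len(self.seq)


class ReadSet(list):
    """A list of :class:`Read` with FASTQ round-trip helpers."""

    def write_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for r in self:
                fh.write(f"@{r.name}\n{r.seq}\n+\n{r.qual}\n")

    @classmethod
    def read_fastq(cls, path) -> "ReadSet":
        from Bio import SeqIO

        return cls(Read(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq"))


def _draw_reads_from_seq(seq: str, starts: np.ndarray, strands: np.ndarray,
                         read_length: int, error_rate: float,
                         rng: np.random.Generator) -> list[str]:
    codes = encode(seq).astype(np.int64)
    idx = starts[:, None] + np.arange(read_length)[None, :]
    mat = codes[idx]
    if strands.any():
        rc = (3 - mat[strands])[:, ::-1]
        mat[strands] = rc
    if error_rate > 0:
        mask = rng.random(mat.shape) < error_rate
        shift = rng.integers(1, 4, size=mat.shape)
        mat[mask] = (mat[mask] + shift[mask]) % 4
    return [decode(row) for row in mat]


def simulate_shotgun_reads(source, params: ReadSimParams) -> ReadSet:
    """Uniform-coverage single-end shotgun reads.

    ``source`` is a :class:`GenomeAssembly` or a :class:`CommunitySpec` whose
    members carry assemblies; for a community, reads are allocated
    proportionally to abundance x genome length.  Start positions are uniform
    over valid positions, strand is uniform, substitution errors i.i.d.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    if isinstance(source, CommunitySpec):
        units: list[tuple[str, str, float]] = []  # (label, seq, weight)
        for m in source.members:
            if m.genome is None:
                raise SpecError(f"member {m.taxon_id} has no genome")
            for cname, seq in m.genome.contigs.items():
                units.append((f"{m.taxon_id}|{cname}", seq, m.abundance * len(seq)))
    else:
        units = [(c, s, float(len(s))) for c, s in source.contigs.items()]

    usable = []
    for label, seq, w in units:
        if len(seq) < params.read_length:
            warnings.warn(f"contig {label} shorter than read length; skipped")
            continue
        usable.append((label, seq, w))
    if not usable:
        raise SpecError("no contig long enough for the requested read length")

    weights = np.array([w for _, _, w in usable])
    probs = weights / weights.sum()
    counts = rng.multinomial(params.n_reads, probs)

    reads = ReadSet()
    serial = 0
    for (label, seq, _), k in zip(usable, counts):
        if k == 0:
            continue
        starts = rng.integers(0, len(seq) - params.read_length + 1, size=k)
        strands = rng.random(k) < 0.5
        seqs = _draw_reads_from_seq(seq, starts, strands, params.read_length,
                                    params.substitution_error_rate, rng)
        for s0, neg, rs in zip(starts, strands, seqs):
            st = "-" if neg else "+"
            reads.append(Read(f"r{serial}|{label}|{s0}|{st}", rs))
            serial += 1
    return reads


# ---------------------------------------------------------------------------
# communities and amplicons


@dataclass
class Member:
    taxon_id: str
    abundance: float
    cn: float = 1.0
    genome: GenomeAssembly | None = None
    its: str | None = None
    species: str | None = None
    genus: str | None = None


@dataclass
class CommunitySpec:
    members: list[Member]
    name: str = "community"

    def __post_init__(self) -> None:
        ids = [m.taxon_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise SpecError("duplicate taxon ids in community")
        total = sum(m.abundance for m in self.members)
        if abs(total - 1.0) > 1e-9:
            raise SpecError(f"abundances sum to {total}, not 1")

    def abundance_profile(self, level: str = "species") -> dict[str, float]:
        out: dict[str, float] = {}
        for m in self.members:
            key = {"species": m.species or m.taxon_id,
                   "genus": m.genus or m.taxon_id,
                   "taxon": m.taxon_id}[level]
            out[key] = out.get(key, 0.0) + m.abundance
        return out


def simulate_its_amplicons(community: CommunitySpec, params: ReadSimParams,
                           its_sequences: dict[str, str] | None = None) -> ReadSet:
    """ITS amplicon reads with the copy-number bias of rDNA amplification:
    member sampling weight is abundance x ITS copy number."""
    params.validate()
    rng = np.random.default_rng(params.seed)

    its: dict[str, str] = {}
    for m in community.members:
        seq = (its_sequences or {}).get(m.taxon_id) or m.its
        if not seq:
            raise SpecError(f"member {m.taxon_id} has no ITS sequence")
        if m.cn <= 0:
            raise SpecError(f"member {m.taxon_id} has non-positive copy number")
        its[m.taxon_id] = seq

    weights = np.array([m.abundance * m.cn for m in community.members])
    probs = weights / weights.sum()
    counts = rng.multinomial(params.n_reads, probs)

    reads = ReadSet()
    serial = 0
    for m, k in zip(community.members, counts):
        if k == 0:
            continue
        seq = its[m.taxon_id]
        rl = min(params.read_length, len(seq))
        starts = rng.integers(0, len(seq) - rl + 1, size=k)
        strands = rng.random(k) < 0.5
        seqs = _draw_reads_from_seq(seq, starts, strands, rl,
                                    params.substitution_error_rate, rng)
        for s0, neg, rs in zip(starts, strands, seqs):
            st = "-" if neg else "+"
            reads.append(Read(f"a{serial}|{m.taxon_id}|{s0}|{st}", rs))
            serial += 1
    return reads


# ---------------------------------------------------------------------------
# compositional counts


@dataclass
class CompositionalSim:
    counts: pd.DataFrame          # samples x taxa, each row sums to depth
    basis_corr: np.ndarray        # the planted basis correlation matrix
    log_basis: np.ndarray         # samples x taxa latent log abundances


def simulate_compositional_counts(n_samples: int, n_taxa: int,
                                  basis_corr_spec=None, depth: int = 10_000,
                                  seed: int = 0, sigma: float = 1.0,
                                  mean_log: float = 0.0) -> CompositionalSim:
    """Log-normal basis abundances with a requested correlation structure,
    closed by multinomial sampling to a fixed depth per sample.

    ``basis_corr_spec`` is None (identity), a list of ``(i, j, rho)`` planted
    pairs, or a full correlation matrix; it must be positive-definite.
    """
    if depth <= 0:
        raise SpecError("depth must be positive")
    corr = np.eye(n_taxa)
    if basis_corr_spec is None:
        pass
    elif isinstance(basis_corr_spec, np.ndarray):
        corr = np.array(basis_corr_spec, dtype=float)
    else:
        for i, j, rho in basis_corr_spec:
            corr[i, j] = corr[j, i] = rho
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise SpecError("basis correlation spec is not positive-definite") from exc

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_samples, n_taxa)) @ chol.T
    log_basis = mean_log + sigma * z
    basis = np.exp(log_basis)
    frac = basis / basis.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, p) for p in frac])
    df = pd.DataFrame(counts,
                      index=[f"sample_{i:03d}" for i in range(n_samples)],
                      columns=[f"taxon_{j:03d}" for j in range(n_taxa)])
    return CompositionalSim(df, corr, log_basis)


# ---------------------------------------------------------------------------
# diet tables

_NUTRIENTS = ["protein_g", "fat_g", "carbohydrate_g", "fiber_g", "sugar_g",
              "iron_mg", "calcium_mg", "zinc_mg", "vitamin_c_mg", "folate_ug"]
_FOOD_GROUPS = ["fruit", "vegetables", "dairy", "fish", "meat", "sweets",
                "cereals", "legumes"]
# kcal per gram for the three energy-bearing macronutrients
_MACRO_KCAL = {"protein_g": 4.0, "fat_g": 9.0, "carbohydrate_g": 4.0}
_MACRO_SHARE = {"protein_g": 0.17, "fat_g": 0.33, "carbohydrate_g": 0.50}


def simulate_diet_profiles(n_subjects: int = 6, n_timepoints: int = 2,
                           n_nutrients: int = 10, n_food_groups: int = 8,
                           noise_sd: float = 0.1, seed: int = 0) -> pd.DataFrame:
    """Longitudinal food-frequency-questionnaire-like tables.

    Each subject has a stable dietary baseline; each administration adds
    multiplicative noise.  Energy is correlated with the macronutrients by
    construction (macronutrient grams scale with the subject's energy intake).
    One row per (subject, timepoint); columns: energy_kcal, ``n_nutrients``
    nutrient columns, ``n_food_groups`` weekly food-group frequencies.
    """
    if n_subjects < 1 or n_timepoints < 1:
        raise SpecError("need at least one subject and one timepoint")
    rng = np.random.default_rng(seed)
    nutrient_cols = (_NUTRIENTS + [f"nutrient_{k:02d}" for k in range(11, n_nutrients + 1)])[:n_nutrients]
    fg_cols = (_FOOD_GROUPS + [f"food_group_{k:02d}" for k in range(9, n_food_groups + 1)])[:n_food_groups]

    rows = []
    for s in range(n_subjects):
        energy0 = rng.normal(2100, 300)
        micro0 = {c: rng.lognormal(np.log(50), 0.4) for c in nutrient_cols
                  if c not in _MACRO_SHARE}
        fg0 = {c: rng.uniform(1, 14) for c in fg_cols}
        for t in range(1, n_timepoints + 1):
            jitter = 1.0 + noise_sd * rng.standard_normal()
            energy = max(energy0 * jitter, 500.0)
            row = {"subject": f"subj_{s + 1:02d}", "timepoint": t,
                   "energy_kcal": energy}
            for c in nutrient_cols:
                if c in _MACRO_SHARE:
                    base = _MACRO_SHARE[c] * energy / _MACRO_KCAL[c]
                else:
                    base = micro0[c]
                row[c] = max(base * (1.0 + noise_sd * rng.standard_normal()), 0.0)
            for c in fg_cols:
                row[c] = max(fg0[c] * (1.0 + noise_sd * rng.standard_normal()), 0.0)
            rows.append(row)
    return pd.DataFrame(rows)
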