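"""CN-MD: ITS copy number from shotgun reads by mapping depth.

A single-copy marker gene is present exactly once per genome, so its mapping
depth calibrates one genome-equivalent of coverage.  The ITS copy number is
then the trimmed-mean depth of the ITS sequence divided by the *median*
trimmed-mean depth of the marker genes (the median avoids bias from outlier
markers).  Depth is computed from MAPQ-filtered alignments (MAPQ >= 30), and
the first and last 50 bp of every gene are trimmed before averaging because
read ends deplete coverage there.

A minimal exact-seed, ungapped, full-length internal aligner is included so
the pipeline runs without an external mapper; standard SAM produced by any
mapper can be ingested instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simkit import Read, ReadSet, encode, revcomp

__all__ = [
    "AlignmentRecord",
    "GeneDepth",
    "CNMDResult",
    "ReferenceIndex",
    "align_reads_minimal",
    "write_sam",
    "read_sam",
    "depth_from_alignments",
    "trimmed_mean_depth",
    "estimate_cn_md",
    "gene_depths",
    "cn_md_pipeline",
]


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    ref_id: str | None
    pos: int = 0                 # 0-based leftmost reference position
    mapq: int = 0                # 0-60; internal aligner: 42 unique, 0 tied
    aligned_length: int = 0      # reference bases consumed
    is_mapped: bool = False
    strand: str = "+"
    n_mismatch: int = 0


@dataclass(frozen=True)
class GeneDepth:
    ref_id: str
    trimmed_mean_depth: float
    usable_length: int


@dataclass
class CNMDResult:
    sample: str
    its_depth: float
    marker_median_depth: float
    cn_md: float

    def to_json_dict(self) -> dict:
        return vars(self)


class ReferenceIndex:
    """Exact k-mer seed index over the forward strands of the references."""

    def __init__(self, references: dict[str, str], seed_length: int = 20):
        if not references:
            raise ValueError("references must be non-empty")
        if seed_length < 4 or seed_length > 31:
            raise ValueError("seed_length must be in [4, 31]")
        self.k = seed_length
        self.names = list(references)
        self.seqs = {n: encode(s).astype(np.int64) for n, s in references.items()}
        self.lengths = {n: len(s) for n, s in references.items()}
        self.index: dict[int, list[tuple[str, int]]] = {}
        pow4 = 4 ** np.arange(seed_length - 1, -1, -1, dtype=np.int64)
        for name, codes in self.seqs.items():
            if codes.size < seed_length:
                continue
            win = np.lib.stride_tricks.sliding_window_view(codes, seed_length)
            valid = (win < 4).all(axis=1)
            keys = win @ pow4
            for p in np.where(valid)[0]:
                self.index.setdefault(int(keys[p]), []).append((name, int(p)))
        self._pow4 = pow4

    def seed_key(self, codes: np.ndarray) -> int | None:
        if codes.size < self.k or (codes[: self.k] >= 4).any():
            return None
        return int(codes[: self.k] @ self._pow4)


def align_reads_minimal(reads, references: dict[str, str], seed_length: int = 20,
                        max_mismatch_frac: float = 0.25,
                        index: ReferenceIndex | None = None) -> list[AlignmentRecord]:
    """Map reads by exact seed + full-length ungapped extension on both strands.

    The first ``seed_length`` bases of the read (or of its reverse complement
    for the minus strand) must match a reference exactly; the whole read is
    then compared ungapped.  A unique best location (fewest mismatches) gets
    MAPQ 42, tied best locations MAPQ 0, no acceptable location -> unmapped.
    Reads longer than every reference are unmapped, not an error.
    """
    idx = index if index is not None else ReferenceIndex(references, seed_length)
    out: list[AlignmentRecord] = []
    for r in reads:
        name, seq = (r.name, r.seq) if isinstance(r, Read) else (r[0], r[1])
        L = len(seq)
        fwd = encode(seq).astype(np.int64)
        rev = encode(revcomp(seq)).astype(np.int64)
        candidates: dict[tuple[str, int, str], int] = {}
        for codes, strand in ((fwd, "+"), (rev, "-")):
            key = idx.seed_key(codes)
            if key is None:
                continue
            for ref, p in idx.index.get(key, ()):
                if p + L > idx.lengths[ref]:
                    continue  # full-length only: overhangs are not aligned
                loc = (ref, p, strand)
                if loc in candidates:
                    continue
                mism = int(np.count_nonzero(idx.seqs[ref][p:p + L] != codes))
                candidates[loc] = mism
        if not candidates:
            out.append(AlignmentRecord(name, None))
            continue
        best = min(candidates.values())
        if best > max_mismatch_frac * L:
            out.append(AlignmentRecord(name, None))
            continue
        winners = [loc for loc, m in candidates.items() if m == best]
        ref, p, strand = winners[0]
        mapq = 42 if len(winners) == 1 else 0
        out.append(AlignmentRecord(name, ref, p, mapq, L, True, strand, best))
    return out


def write_sam(records: list[AlignmentRecord], references: dict[str, str], path,
              reads=None) -> None:
    """Write records as SAM (via pysam).  ``reads`` (optional, same order)
    supplies sequences; otherwise '*' is written."""
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": n, "LN": len(s)} for n, s in references.items()]}
    ref_ids = {n: i for i, n in enumerate(references)}
    seq_by_name = {}
    if reads is not None:
        for r in reads:
            seq_by_name[r.name] = r.seq
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for rec in records:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = rec.read_id
            seq = seq_by_name.get(rec.read_id)
            if rec.is_mapped:
                a.reference_id = ref_ids[rec.ref_id]
                a.reference_start = rec.pos
                a.mapping_quality = rec.mapq
                a.cigarstring = f"{rec.aligned_length}M"
                a.flag = 16 if rec.strand == "-" else 0
                if seq is not None:
                    a.query_sequence = revcomp(seq) if rec.strand == "-" else seq
                a.set_tag("NM", rec.n_mismatch)
            else:
                a.flag = 4
                if seq is not None:
                    a.query_sequence = seq
            fh.write(a)


def read_sam(path) -> tuple[list[AlignmentRecord], dict[str, int]]:
    """Ingest SAM.  Soft/hard clips are honoured: aligned_length is the
    reference span of the alignment."""
    import pysam

    records = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        lengths = dict(zip(fh.references, fh.lengths))
        for a in fh:
            if a.is_unmapped:
                records.append(AlignmentRecord(a.query_name, None))
            else:
                records.append(AlignmentRecord(
                    a.query_name, a.reference_name, a.reference_start,
                    a.mapping_quality, a.reference_length or 0, True,
                    "-" if a.is_reverse else "+"))
    return records, lengths


def depth_from_alignments(records: list[AlignmentRecord],
                          ref_lengths: dict[str, int],
                          mapq_min: int = 30) -> dict[str, np.ndarray]:
    """Per-base depth per reference; unmapped and MAPQ < ``mapq_min`` records
    contribute nothing.  Records running past the reference end are clipped
    with a warning."""
    starts: dict[str, list[int]] = {n: [] for n in ref_lengths}
    ends: dict[str, list[int]] = {n: [] for n in ref_lengths}
    clipped = 0
    for rec in records:
        if not rec.is_mapped or rec.mapq < mapq_min:
            continue
        if rec.ref_id not in ref_lengths:
            raise KeyError(f"alignment references unknown sequence {rec.ref_id!r}")
        L = ref_lengths[rec.ref_id]
        s = rec.pos
        e = rec.pos + rec.aligned_length
        if e > L:
            e = L
            clipped += 1
        if s < e:
            starts[rec.ref_id].append(s)
            ends[rec.ref_id].append(e)
    if clipped:
        warnings.warn(f"{clipped} alignments extended past the reference end; clipped")
    depth = {}
    for name, L in ref_lengths.items():
        diff = np.zeros(L + 1, dtype=np.int64)
        if starts[name]:
            np.add.at(diff, np.array(starts[name]), 1)
            np.add.at(diff, np.array(ends[name]), -1)
        depth[name] = np.cumsum(diff)[:L]
    return depth


def trimmed_mean_depth(depth_vector: np.ndarray, trim: int = 50,
                       ref_id: str = "gene") -> GeneDepth:
    """Mean depth over positions [trim, L - trim); gene ends are excluded
    because fewer reads fit there."""
    L = len(depth_vector)
    if L <= 2 * trim:
        raise ValueError(
            f"reference length {L} <= 2*trim ({2 * trim}); lower the trim")
    window = np.asarray(depth_vector[trim:L - trim], dtype=float)
    return GeneDepth(ref_id, float(window.mean()), L - 2 * trim)


def estimate_cn_md(its: GeneDepth, markers: list[GeneDepth],
                   sample: str = "sample") -> CNMDResult:
    """Copy number = ITS depth / median marker depth."""
    if not markers:
        raise ValueError("need at least one marker gene depth")
    med = float(np.median([m.trimmed_mean_depth for m in markers]))
    if med <= 0:
        raise ValueError("marker median depth is 0: copy number undefined")
    return CNMDResult(sample, its.trimmed_mean_depth, med,
                      its.trimmed_mean_depth / med)


def gene_depths(records: list[AlignmentRecord], ref_lengths: dict[str, int],
                mapq_min: int = 30, trim: int = 50) -> dict[str, GeneDepth]:
    """MAPQ-filtered, end-trimmed mean depth for every reference gene."""
    table = depth_from_alignments(records, ref_lengths, mapq_min)
    return {n: trimmed_mean_depth(v, trim, n) for n, v in table.items()}


def cn_md_pipeline(reads: ReadSet, its_refs: dict[str, str],
                   marker_refs: dict[str, str], mapq_min: int = 30,
                   trim: int = 50, seed_length: int = 20,
                   sample: str = "sample") -> CNMDResult:
    """Reads -> alignment -> depth -> CN-MD, against ITS + marker references
    jointly (so multi-mapping between them is resolved by the MAPQ-0 rule)."""
    refs = {**its_refs, **marker_refs}
    records = align_reads_minimal(reads, refs, seed_length)
    depths = gene_depths(records, {n: len(s) for n, s in refs.items()},
                         mapq_min, trim)
    its_parts = [depths[n] for n in its_refs]
    if len(its_parts) == 1:
        its = its_parts[0]
    else:  # length-weighted combination of several ITS references
        tot = sum(g.usable_length for g in its_parts)
        mean = sum(g.trimmed_mean_depth * g.usable_length for g in its_parts) / tot
        its = GeneDepth("ITS", mean, tot)
    markers = [depths[n] for n in marker_refs]
    return estimate_cn_md(its, markers, sample=sample)
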