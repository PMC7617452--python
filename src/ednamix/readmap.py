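"""Desk-scale end-to-end read mapping, SAM ingest/emit, alignment filters and
the competitive multi-reference partition."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .util import revcomp, seq_to_array

UNIQUE_MAP_SCORE = 37  # surrogate quality for a unique best placement


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    ref_id: str
    start: int  # 0-based leftmost
    strand: str  # '+' or '-'
    aligned_length: int
    edit_distance: int
    map_score: int  # 0 when the best placement is tied


@dataclass
class MappingStats:
    n_mapped: int = 0
    n_unmapped: int = 0
    n_skipped_short: int = 0


@dataclass
class PartitionResult:
    """Disjoint read sets from competitive mapping against k references."""

    ref_ids: list[str]
    unique: dict[str, set]  # ref_id -> read ids mapped (or arbitrated) to it alone
    shared: set
    n_unmapped: int
    mode: str

    @property
    def unique_a(self) -> set:
        return self.unique[self.ref_ids[0]]

    @property
    def unique_b(self) -> set:
        return self.unique[self.ref_ids[1]]

    def validate(self, n_input_reads: int) -> None:
        sets = list(self.unique.values()) + [self.shared]
        total = sum(len(s) for s in sets)
        union = set().union(*sets)
        if total != len(union):
            raise AssertionError("partition sets overlap")
        if total + self.n_unmapped != n_input_reads:
            raise AssertionError("partition does not cover the read universe")


# ---------------------------------------------------------------------------
# mini-mapper

_DAMAGE_HALF = {("+", ord("C"), ord("T")), ("-", ord("G"), ord("A"))}


def _score_strand(ref_arr: np.ndarray, read: str, strand: str,
                  damage_tolerant: bool) -> tuple[np.ndarray, np.ndarray]:
    """(weighted score, raw mismatches) for every end-to-end placement."""
    read_arr = seq_to_array(read)
    L = len(read_arr)
    windows = np.lib.stride_tricks.sliding_window_view(ref_arr, L)
    valid = np.isin(read_arr, seq_to_array("ACGT"))
    mism = (windows != read_arr) | ~valid
    raw = mism.sum(axis=1)
    if not damage_tolerant:
        return raw.astype(float), raw
    weights = np.ones(windows.shape, dtype=np.float32)
    for s, ref_b, read_b in _DAMAGE_HALF:
        if s == strand:
            weights[(windows == ref_b) & (read_arr == read_b) & valid] = 0.5
    return np.where(mism, weights, 0.0).sum(axis=1), raw


def map_read(read_id: str, read: str, ref_id: str, ref_arr: np.ndarray,
             max_mismatch_rate: float, damage_tolerant: bool) -> AlignmentRecord | None:
    """Exhaustive best end-to-end placement on both strands, or None.

    Ties on the best score leave one deterministic placement (lowest start,
    then '+' strand) with map_score 0.
    """
    L = len(read)
    if L > len(ref_arr):
        return None
    budget = math.ceil(max_mismatch_rate * L)
    best = None  # (score, start, strand_rank, raw)
    n_best = 0
    for strand, oriented in (("+", read), ("-", revcomp(read))):
        score, raw = _score_strand(ref_arr, oriented, strand, damage_tolerant)
        ok = np.flatnonzero(score <= budget)
        if ok.size == 0:
            continue
        smin = score[ok].min()
        hits = ok[score[ok] == smin]
        cand = (smin, int(hits[0]), 0 if strand == "+" else 1, int(raw[hits[0]]))
        if best is None or cand[0] < best[0]:
            best, n_best = cand, int(hits.size)
        elif cand[0] == best[0]:
            n_best += int(hits.size)
            if (cand[1], cand[2]) < (best[1], best[2]):
                best = cand
    if best is None:
        return None
    score, start, strand_rank, raw = best
    return AlignmentRecord(read_id, ref_id, start, "+" if strand_rank == 0 else "-",
                           L, raw, UNIQUE_MAP_SCORE if n_best == 1 else 0)


def map_reads_end_to_end(reads, reference: tuple[str, str],
                         max_mismatch_rate: float = 0.1, min_len: int = 35,
                         damage_tolerant: bool = False) -> tuple[list[AlignmentRecord], MappingStats]:
    """Map a read collection end-to-end against one reference sequence.

    ``reads`` is a dict id->sequence, an iterable of (id, sequence) pairs, or a
    simdata ``AncientReadSet``.  Substitution-only scoring; gaps are out of
    scope by design.
    """
    ref_id, ref_seq = reference
    if not ref_seq:
        raise ValueError("empty reference")
    if hasattr(reads, "sequences"):
        reads = reads.sequences()
    if isinstance(reads, dict):
        reads = reads.items()
    ref_arr = seq_to_array(ref_seq)
    records, stats = [], MappingStats()
    for read_id, seq in reads:
        if len(seq) < min_len:
            stats.n_skipped_short += 1
            continue
        rec = map_read(read_id, seq.upper(), ref_id, ref_arr, max_mismatch_rate,
                       damage_tolerant)
        if rec is None:
            stats.n_unmapped += 1
        else:
            records.append(rec)
            stats.n_mapped += 1
    return records, stats


def truth_alignments(read_set, ref_id: str = "truth") -> list[AlignmentRecord]:
    """Perfect alignments straight from simulation truth (no mapping)."""
    return [AlignmentRecord(r.id, ref_id, r.start, r.strand, r.end - r.start,
                            len(r.damage_offsets) + len(r.error_offsets),
                            UNIQUE_MAP_SCORE)
            for r in read_set]


# ---------------------------------------------------------------------------
# SAM interchange (text SAM; NM required on read, emitted on write)


def write_sam(path, records: list[AlignmentRecord], reads: dict[str, str],
              reference_lengths: dict[str, int]) -> None:
    """Emit SAM v1; minus-strand reads are stored reverse-complemented."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for rid, length in reference_lengths.items():
            fh.write(f"@SQ\tSN:{rid}\tLN:{length}\n")
        for rec in records:
            seq = reads[rec.read_id]
            flag = 0
            if rec.strand == "-":
                seq = revcomp(seq)
                flag |= 16
            fh.write("\t".join([
                rec.read_id, str(flag), rec.ref_id, str(rec.start + 1),
                str(rec.map_score), f"{rec.aligned_length}M", "*", "0", "0",
                seq, "*", f"NM:i:{rec.edit_distance}",
            ]) + "\n")


def _nm_from_md(md: str) -> int:
    n, i = 0, 0
    while i < len(md):
        c = md[i]
        if c.isdigit():
            i += 1
        elif c == "^":  # deletion run
            i += 1
            while i < len(md) and md[i].isalpha():
                n += 1
                i += 1
        else:
            n += 1
            i += 1
    return n


def read_sam(path) -> tuple[list[AlignmentRecord], dict[str, str], dict[str, int]]:
    """Parse a SAM file into records + read-oriented sequences + ref lengths.

    Requires NM per aligned record; falls back to the MD tag, otherwise raises.
    """
    import pysam

    records: list[AlignmentRecord] = []
    reads: dict[str, str] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        ref_lengths = dict(zip(sam.references, sam.lengths))
        for i, aln in enumerate(sam.fetch(until_eof=True), 1):
            if aln.is_unmapped:
                continue
            if aln.has_tag("NM"):
                nm = int(aln.get_tag("NM"))
            elif aln.has_tag("MD"):
                nm = _nm_from_md(str(aln.get_tag("MD")))
            else:
                raise ValueError(
                    f"alignment {i} ({aln.query_name}): neither NM nor MD present")
            strand = "-" if aln.is_reverse else "+"
            seq = aln.query_sequence or ""
            if aln.is_reverse:
                seq = revcomp(seq)
            mapq = aln.mapping_quality
            records.append(AlignmentRecord(aln.query_name, aln.reference_name,
                                           aln.reference_start, strand,
                                           aln.query_length, nm, mapq))
            reads[aln.query_name] = seq
    return records, reads, ref_lengths


# ---------------------------------------------------------------------------
# filters and partition


@dataclass
class FilterCounts:
    kept: int = 0
    removed_map_score: int = 0
    removed_length: int = 0


def filter_alignments(records: list[AlignmentRecord], min_map_score: int = 25,
                      min_len: int = 35) -> tuple[list[AlignmentRecord], FilterCounts]:
    """Keep records with map_score >= min_map_score and length >= min_len."""
    kept, counts = [], FilterCounts()
    for rec in records:
        if rec.map_score < min_map_score:
            counts.removed_map_score += 1
        elif rec.aligned_length < min_len:
            counts.removed_length += 1
        else:
            kept.append(rec)
            counts.kept += 1
    return kept, counts


def _by_read(records: list[AlignmentRecord], ref_id: str) -> dict[str, AlignmentRecord]:
    out: dict[str, AlignmentRecord] = {}
    for rec in records:
        prev = out.get(rec.read_id)
        if prev is not None and prev != rec:
            raise ValueError(f"conflicting records for read {rec.read_id!r} on {ref_id!r}")
        out[rec.read_id] = rec
    return out


def competitive_partition(alignments: dict[str, list[AlignmentRecord]],
                          read_universe: set[str],
                          mode: str = "presence") -> PartitionResult:
    """Partition the read universe by which references accepted each read.

    presence: unique_i = mapped to reference i only; shared = mapped to >= 2.
    edit_arbitration: a multiply-mapped read goes to the reference with
    strictly smallest edit distance; any tie for the minimum -> shared.
    """
    if mode not in ("presence", "edit_arbitration"):
        raise ValueError(f"unknown mode {mode!r}")
    ref_ids = list(alignments)
    if len(ref_ids) < 2:
        raise ValueError("need at least two references")
    per_ref = {rid: _by_read(recs, rid) for rid, recs in alignments.items()}
    unique: dict[str, set] = {rid: set() for rid in ref_ids}
    shared: set = set()
    n_unmapped = 0
    for read_id in read_universe:
        hits = [(rid, per_ref[rid][read_id]) for rid in ref_ids if read_id in per_ref[rid]]
        if not hits:
            n_unmapped += 1
        elif len(hits) == 1:
            unique[hits[0][0]].add(read_id)
        elif mode == "presence":
            shared.add(read_id)
        else:
            edits = [(rec.edit_distance, rid) for rid, rec in hits]
            best = min(e for e, _ in edits)
            winners = [rid for e, rid in edits if e == best]
            if len(winners) == 1:
                unique[winners[0]].add(read_id)
            else:
                shared.add(read_id)
    result = PartitionResult(ref_ids, unique, shared, n_unmapped, mode)
    result.validate(len(read_universe))
    return result


def extract_read_subset(fastq_records: list[tuple[str, str]],
                        ids: set[str]) -> list[tuple[str, str]]:
    """Order-preserving subset of FASTQ records; unknown ids are an error."""
    present = {name for name, _ in fastq_records}
    missing = sorted(ids - present)
    if missing:
        raise KeyError(f"read ids absent from FASTQ: {missing}")
    return [(name, seq) for name, seq in fastq_records if name in ids]
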