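"""Raw small-RNA reads to a mature-miRNA counts matrix.

The processing chain mirrors standard small-RNA practice for a miRBase-style
annotation: 3' adapter trimming, a 15-35 nt length filter, exhaustive
ungapped alignment to hairpin precursors with at most one mismatch (sense
strand only), assignment of a read to a mature miRNA when both of its ends
fall within 3 nt of the annotated mature ends (isomiR tolerance), genome
re-alignment to re-assign reads with a strictly better match outside any
miRNA locus, and GENCODE-style categorization of everything that is not a
miRNA.  Every input read receives exactly one fate, so the per-sample
tallies partition the library.

Alignment semantics are defined by :func:`align_ungapped` (a naive
every-offset Hamming scan); the pipeline runs the same scan vectorized over
a concatenated target text, with an exact-substring fast path, and skips the
genome pass for reads whose hairpin hit is already perfect (no strictly
better hit can exist).
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from numpy.lib.stride_tricks import sliding_window_view

from mirdel import formats
from mirdel.simulate import ADAPTER, Hairpin, ToyReference, revcomp

logger = logging.getLogger(__name__)

#: Category precedence when a read's best genome hits overlap several features.
CATEGORY_PRIORITY = ["snoRNA", "tRNA", "rRNA", "lincRNA", "protein_coding", "intergenic"]

#: Exhaustive, ordered read-fate vocabulary.
FATES = ["adapterless", "length_filtered", "miRNA", "ambiguous"] + CATEGORY_PRIORITY + ["unmapped"]


@dataclass(frozen=True)
class TrimmedRead:
    id: str
    sequence: str
    adapter_found: bool
    original_length: int


@dataclass(frozen=True)
class AlignmentHit:
    """Ungapped hit of a read on a hairpin or genome contig (1-based start)."""

    target_kind: str  # "hairpin" | "genome"
    target_id: str
    start: int
    strand: str
    mismatches: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass(frozen=True)
class MatureAssignment:
    mature_id: str
    offset5: int
    offset3: int
    mismatches: int


@dataclass
class QuantifyParams:
    """Trimming / alignment / assignment parameters.

    The end tolerance of 3 nt admits isomiRs whose 5' and 3' ends are each
    within 3 nt of the annotated mature ends (exact ends included).
    """

    adapter: str = ADAPTER
    min_overlap: int = 6
    max_mismatch_rate: float = 0.1
    min_len: int = 15
    max_len: int = 35
    max_mismatches: int = 1
    end_tolerance: int = 3

    def validate(self) -> None:
        if not (5 <= self.min_overlap <= len(self.adapter)):
            raise ValueError("need adapter length >= min_overlap >= 5")
        if self.max_mismatch_rate < 0 or self.max_mismatch_rate > 1:
            raise ValueError("max_mismatch_rate must lie in [0, 1]")


@dataclass
class QuantifyResult:
    """Counts matrix plus the per-sample read-fate report."""

    counts: pd.DataFrame  # mature_id x sample, integer
    fate_report: pd.DataFrame  # sample x fate, integer; includes 'total'

    @property
    def assigned_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def fate_fractions(self) -> pd.DataFrame:
        tallies = self.fate_report[FATES]
        return tallies.div(self.fate_report["total"], axis=0)


# ---------------------------------------------------------------------------
# adapter trimming and length filter


def trim_adapter(
    sequence: str,
    adapter: str = ADAPTER,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
    read_id: str = "",
) -> TrimmedRead:
    """Trim the 3' adapter at the leftmost tolerated match position.

    A position qualifies when a prefix of the adapter — truncated where the
    adapter runs off the read's 3' end, but at least ``min_overlap`` long —
    matches with a mismatch rate of at most ``max_mismatch_rate``.
    """
    n, a = len(sequence), len(adapter)
    exact = sequence.find(adapter)
    limit = exact if exact >= 0 else n - min_overlap
    for i in range(0, limit + 1):
        k = min(a, n - i)
        if k < min_overlap:
            break
        budget = max_mismatch_rate * k
        mm = 0
        for x, y in zip(sequence[i : i + k], adapter):
            if x != y:
                mm += 1
                if mm > budget:
                    break
        else:
            return TrimmedRead(read_id, sequence[:i], True, n)
    if exact >= 0:
        return TrimmedRead(read_id, sequence[:exact], True, n)
    return TrimmedRead(read_id, sequence, False, n)


def filter_length(
    reads: Iterable[TrimmedRead], min_len: int = 15, max_len: int = 35
) -> tuple[list[TrimmedRead], dict[str, int]]:
    """Keep reads with trimmed length in [min_len, max_len]; tally both fates."""
    kept, tally = [], {"kept": 0, "filtered": 0}
    for r in reads:
        if min_len <= len(r.sequence) <= max_len:
            kept.append(r)
            tally["kept"] += 1
        else:
            tally["filtered"] += 1
    return kept, tally


# ---------------------------------------------------------------------------
# ungapped alignment


class _ConcatIndex:
    """All targets in one text with 'NNNN' separators; one vectorized scan.

    Windows that would span a target boundary are mapped back and rejected,
    so hits agree exactly with a per-target every-offset scan.
    """

    SEP = "NNNN"

    def __init__(self, targets: Mapping[str, str], kind: str, both_strands: bool):
        self.kind = kind
        self.both_strands = both_strands
        self.names = list(targets)
        self.lengths = [len(targets[n]) for n in self.names]
        self.starts = []  # 0-based offset of each target in the concat text
        parts, pos = [], 0
        for name in self.names:
            self.starts.append(pos)
            parts.append(targets[name])
            pos += len(targets[name]) + len(self.SEP)
            parts.append(self.SEP)
        self.text = "".join(parts)
        self.arr = np.frombuffer(self.text.encode(), dtype=np.uint8)

    def _map(self, pos0: int, length: int) -> tuple[str, int] | None:
        i = bisect_right(self.starts, pos0) - 1
        off = pos0 - self.starts[i]
        if off + length <= self.lengths[i]:
            return self.names[i], off + 1
        return None

    def _hits_at(self, positions: Iterable[int], length: int, strand: str, mm_at) -> list[AlignmentHit]:
        hits = []
        for p in positions:
            mapped = self._map(int(p), length)
            if mapped is not None:
                name, start = mapped
                hits.append(AlignmentHit(self.kind, name, start, strand, int(mm_at(p)), length))
        return hits

    def _scan_one(self, seq: str, max_mm: int, strand: str) -> list[AlignmentHit]:
        L = len(seq)
        if L == 0 or L > len(self.arr):
            return []
        read = np.frombuffer(seq.encode(), dtype=np.uint8)
        mm = (sliding_window_view(self.arr, L) != read).sum(axis=1)
        pos = np.nonzero(mm <= max_mm)[0]
        return self._hits_at(pos, L, strand, lambda p: mm[p])

    def scan(self, seq: str, max_mm: int) -> list[AlignmentHit]:
        hits = self._scan_one(seq, max_mm, "+")
        if self.both_strands:
            hits += self._scan_one(revcomp(seq), max_mm, "-")
        hits.sort(key=lambda h: (h.mismatches, h.target_id, h.start, h.strand))
        return hits

    def find_exact(self, seq: str) -> list[AlignmentHit]:
        """All 0-mismatch hits via C-level substring search."""
        out = []
        for query, strand in [(seq, "+")] + ([(revcomp(seq), "-")] if self.both_strands else []):
            if not query:
                continue
            i = self.text.find(query)
            positions = []
            while i >= 0:
                positions.append(i)
                i = self.text.find(query, i + 1)
            out += self._hits_at(positions, len(query), strand, lambda p: 0)
        out.sort(key=lambda h: (h.mismatches, h.target_id, h.start, h.strand))
        return out


def align_ungapped(
    read: str,
    targets: Mapping[str, str],
    max_mismatches: int = 1,
    both_strands: bool = False,
    target_kind: str = "hairpin",
) -> list[AlignmentHit]:
    """Exhaustive ungapped scan of every offset of every target.

    Returns all hits with at most ``max_mismatches`` substitutions, with the
    exact mismatch count; minus-strand hits (genome mode) align the read's
    reverse complement and report plus-strand coordinates.  Ambiguous bases
    count as mismatches.
    """
    idx = _ConcatIndex(targets, target_kind, both_strands)
    return idx.scan(read, max_mismatches)


# ---------------------------------------------------------------------------
# mature assignment and cross-mapping resolution


def _candidate_assignments(
    hit: AlignmentHit, hairpin: Hairpin, tolerance: int
) -> list[MatureAssignment]:
    out = []
    for mid, ms, me in hairpin.matures:
        off5 = hit.start - ms
        off3 = hit.end - me
        if abs(off5) <= tolerance and abs(off3) <= tolerance:
            out.append(MatureAssignment(mid, off5, off3, hit.mismatches))
    out.sort(key=lambda a: abs(a.offset5) + abs(a.offset3))
    return out


def assign_mature(
    hit: AlignmentHit, hairpin: Hairpin, tolerance: int = 3
) -> MatureAssignment | None:
    """Assign a hairpin hit to a mature miRNA under the end-offset rule.

    Both read ends must lie within ``tolerance`` nt of the mature ends; the
    qualifying mature with the smallest total end offset wins, and an exact
    tie between distinct matures discards the read (returns None, logged).
    """
    cands = _candidate_assignments(hit, hairpin, tolerance)
    if not cands:
        return None
    if len(cands) > 1:
        k0 = abs(cands[0].offset5) + abs(cands[0].offset3)
        k1 = abs(cands[1].offset5) + abs(cands[1].offset3)
        if k0 == k1:
            logger.info("ambiguous mature assignment on %s at %d", hairpin.id, hit.start)
            return None
    return cands[0]


def resolve_cross_mapping(
    assignment: MatureAssignment,
    genome_hits: Sequence[AlignmentHit],
    mirna_loci: Mapping[str, Sequence[tuple[int, int]]],
) -> bool:
    """True if the miRNA assignment survives genome re-alignment.

    The read is re-assigned as non-miRNA only when its best genome hit lying
    outside every annotated miRNA locus has strictly fewer mismatches than
    the hairpin hit; an equal mismatch count keeps the assignment.
    """
    outside = [h for h in genome_hits if not _hit_in_loci(h, mirna_loci)]
    if not outside:
        return True
    return min(h.mismatches for h in outside) >= assignment.mismatches


def _hit_in_loci(hit: AlignmentHit, loci: Mapping[str, Sequence[tuple[int, int]]]) -> bool:
    for s, e in loci.get(hit.target_id, ()):
        if hit.start <= e and hit.end >= s:
            return True
    return False


def categorize_unassigned(
    genome_hits: Sequence[AlignmentHit],
    feature_trees: Mapping[str, IntervalTree],
) -> str:
    """Category of the feature(s) overlapping the read's best genome hits.

    Among the minimum-mismatch hits, every gene feature overlapping by at
    least 1 bp contributes its category; precedence is snoRNA > tRNA > rRNA
    > lincRNA > protein_coding > intergenic.  Hits in unannotated sequence
    are 'intergenic'; reads with no hit at all are 'unmapped'.
    """
    if not genome_hits:
        return "unmapped"
    best = min(h.mismatches for h in genome_hits)
    cats = set()
    for h in genome_hits:
        if h.mismatches != best:
            continue
        tree = feature_trees.get(h.target_id)
        if tree is not None:
            for iv in tree.overlap(h.start, h.end + 1):
                cats.add(iv.data)
    for cat in CATEGORY_PRIORITY:
        if cat in cats:
            return cat
    return "intergenic"


# ---------------------------------------------------------------------------
# full pipeline


def _feature_trees(ref: ToyReference) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for contig, s, e, _, cat in ref.gene_features:
        trees.setdefault(contig, IntervalTree())[s : e + 1] = cat
    return trees


def _mirna_loci(ref: ToyReference) -> dict[str, list[tuple[int, int]]]:
    loci: dict[str, list[tuple[int, int]]] = {}
    for hp in ref.hairpins:
        contig, s, e, _ = hp.locus
        loci.setdefault(contig, []).append((s, e))
    return loci


def _classify_read(
    raw: str,
    hp_index: _ConcatIndex,
    genome_index: _ConcatIndex,
    hairpin_map: Mapping[str, Hairpin],
    mirna_loci: Mapping[str, Sequence[tuple[int, int]]],
    feature_trees: Mapping[str, IntervalTree],
    params: QuantifyParams,
) -> tuple[str, str | None]:
    """Fate of one read sequence: (fate label, mature_id or None)."""
    trimmed = trim_adapter(raw, params.adapter, params.min_overlap, params.max_mismatch_rate)
    if not (params.min_len <= len(trimmed.sequence) <= params.max_len):
        return ("length_filtered" if trimmed.adapter_found else "adapterless"), None
    seq = trimmed.sequence

    candidates: list[MatureAssignment] = []
    for hit in hp_index.scan(seq, params.max_mismatches):
        candidates += _candidate_assignments(hit, hairpin_map[hit.target_id], params.end_tolerance)
    if candidates:
        candidates.sort(key=lambda a: (a.mismatches, abs(a.offset5) + abs(a.offset3)))
        best = candidates[0]
        tied = {
            a.mature_id
            for a in candidates
            if (a.mismatches, abs(a.offset5) + abs(a.offset3))
            == (best.mismatches, abs(best.offset5) + abs(best.offset3))
        }
        if len(tied) > 1:
            return "ambiguous", None
        if best.mismatches == 0:
            # no genome hit can be strictly better than a perfect hairpin hit
            return "miRNA", best.mature_id
        exact = genome_index.find_exact(seq)
        if resolve_cross_mapping(best, exact, mirna_loci):
            return "miRNA", best.mature_id
        return categorize_unassigned(exact, feature_trees), None

    hits = genome_index.find_exact(seq)
    if not hits:
        hits = genome_index.scan(seq, params.max_mismatches)
    return categorize_unassigned(hits, feature_trees), None


def build_counts(
    records: Iterable[tuple[str, str, str | None, int]],
    mature_ids: Sequence[str],
    samples: Sequence[str],
) -> QuantifyResult:
    """Aggregate per-read fates into the counts matrix and fate report.

    ``records`` yields ``(sample, fate, mature_id, multiplicity)``; the fate
    report partitions every read exactly once and the counts matrix column
    sums equal the per-sample miRNA tallies.
    """
    counts = pd.DataFrame(0, index=list(mature_ids), columns=list(samples), dtype=np.int64)
    fate = pd.DataFrame(0, index=list(samples), columns=["total"] + FATES, dtype=np.int64)
    for sample, label, mature, mult in records:
        fate.loc[sample, "total"] += mult
        fate.loc[sample, label] += mult
        if label == "miRNA":
            counts.loc[mature, sample] += mult
    for sample in samples:
        if fate.loc[sample, "miRNA"] == 0:
            warnings.warn(f"sample {sample}: zero reads assigned to miRNAs", stacklevel=2)
    return QuantifyResult(counts=counts, fate_report=fate)


def quantify(
    fastq_paths: Mapping[str, object],
    ref: ToyReference,
    params: QuantifyParams | None = None,
) -> QuantifyResult:
    """Run the full read-to-counts pipeline over per-sample FASTQ files.

    Identical sequences are collapsed and classified once (the chain is a
    pure function of the sequence), then expanded back into the tallies, so
    the result is independent of read order.
    """
    params = params or QuantifyParams()
    params.validate()
    hp_index = _ConcatIndex({hp.id: hp.sequence for hp in ref.hairpins}, "hairpin", False)
    genome_index = _ConcatIndex(ref.genome, "genome", True)
    hairpin_map = {hp.id: hp for hp in ref.hairpins}
    loci = _mirna_loci(ref)
    trees = _feature_trees(ref)
    cache: dict[str, tuple[str, str | None]] = {}

    def records():
        for sample, path in fastq_paths.items():
            tally = Counter(seq for _, seq, _ in formats.read_fastq(path))
            n_unique, n_total = len(tally), sum(tally.values())
            for seq, mult in tally.items():
                if seq not in cache:
                    cache[seq] = _classify_read(
                        seq, hp_index, genome_index, hairpin_map, loci, trees, params
                    )
                label, mature = cache[seq]
                yield sample, label, mature, mult
            logger.info("%s: %d reads (%d unique) classified", sample, n_total, n_unique)

    return build_counts(records(), ref.mature_ids(), list(fastq_paths))
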