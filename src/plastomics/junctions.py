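"""IR/SC boundary detection and junction-span accounting.

The two inverted repeats of a plastome are located directly from sequence as
the longest pair of disjoint substrings that are exact reverse complements
of each other (length >= ``min_ir_length``, default 1 kb).  Detection is
exact-match: when the two IR copies differ by internal SNPs the detector
reports the longest exact core, which is the appropriate behaviour for taxa
whose IRs are identical in length.

Input plastomes must be linearized at the conventional origin (LSC start),
so the quadripartite frame reads LSC -> IRb -> SSC -> IRa left to right and
IRa ends at the last base.  The longer intervening single-copy stretch is
labelled LSC; on a tie the stretch containing position 1 wins, with a
warning.

Gene positioning across the four junctions (LSC/IRb, IRb/SSC, SSC/IRa,
IRa/LSC) is quantified as the bp span on either side of each crossed
boundary, and across-species junction movement is summarised as the range
(max - min) of each region class's length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from .core import (
    GeneAnnotation,
    Interval,
    PlastomeError,
    RegionPartition,
    reverse_complement,
)

JUNCTION_NAMES = ("LSC/IRb", "IRb/SSC", "SSC/IRa", "IRa/LSC")


# ---------------------------------------------------------------------------
# Inverted-repeat detection
# ---------------------------------------------------------------------------

def _common_substring_pairs(seq: str, rc: str, length: int) -> list[tuple[int, int]]:
    """All (i, j) with seq[i:i+length] == rc-image at j, i.e. the forward
    interval [i, i+length) matches the reverse complement of [j, j+length).

    Offsets are 0-based start positions in *seq* of the two copies, i < j
    and the intervals disjoint.
    """
    n = len(seq)
    index: dict[int, list[int]] = {}
    base = 1000003
    mod = (1 << 61) - 1
    pw = pow(base, length - 1, mod)

    def rolling_positions(s: str) -> "list[tuple[int, int]]":
        out = []
        h = 0
        for k, ch in enumerate(s[:length]):
            h = (h * base + ord(ch)) % mod
        out.append((h, 0))
        for k in range(length, len(s)):
            h = ((h - ord(s[k - length]) * pw) * base + ord(s[k])) % mod
            out.append((h, k - length + 1))
        return out

    for h, pos in rolling_positions(seq):
        index.setdefault(h, []).append(pos)
    pairs = []
    for h, p in rolling_positions(rc):
        # rc position p of length L corresponds to seq interval starting n-p-L
        j = n - p - length
        for i in index.get(h, ()):
            if seq[i : i + length] != rc[p : p + length]:
                continue
            lo, hi = min(i, j), max(i, j)
            if lo + length <= hi:  # disjoint
                pairs.append((lo, hi))
    return sorted(set(pairs))


def detect_inverted_repeats(sequence: str, min_ir_length: int = 1000) -> RegionPartition:
    """Locate the IR pair and return the full quadripartite partition.

    Finds the longest pair of disjoint exact reverse-complement substrings
    (binary search on length with rolling-hash matching, hash hits verified
    by direct comparison).  Raises when no pair of at least *min_ir_length*
    exists, or when the detected structure cannot be expressed as
    LSC -> IRb -> SSC -> IRa in the given linearization.
    """
    seq = sequence.upper()
    n = len(seq)
    if n <= 2 * min_ir_length:
        raise PlastomeError(
            f"sequence of {n} bp cannot contain two disjoint IRs of >= {min_ir_length} bp"
        )
    rc = reverse_complement(seq)

    if not _common_substring_pairs(seq, rc, min_ir_length):
        raise PlastomeError(
            f"no quadripartite structure: no disjoint reverse-complement pair "
            f">= {min_ir_length} bp"
        )
    lo, hi = min_ir_length, n // 2
    while lo < hi:  # largest L with a qualifying pair
        mid = (lo + hi + 1) // 2
        if _common_substring_pairs(seq, rc, mid):
            lo = mid
        else:
            hi = mid - 1
    length = lo
    i, j = _common_substring_pairs(seq, rc, length)[0]

    irb = Interval(i + 1, i + length)
    ira = Interval(j + 1, j + length)
    inner_len = ira.start - irb.end - 1  # between the IR copies
    outer_len = n - (ira.end - irb.start + 1)  # wraps the origin circularly
    if outer_len < inner_len:
        raise PlastomeError(
            "detected single-copy regions imply the LSC lies between the IR "
            "copies; re-linearize the plastome at the LSC start"
        )
    if outer_len == inner_len:
        warnings.warn(
            "single-copy regions tie in length; labelling the stretch "
            "containing position 1 as LSC"
        )
    if irb.start == 1 or ira.end != n:
        raise PlastomeError(
            "plastome is not linearized at the LSC start (IRa must end at the "
            "last base); rotate the sequence to the conventional origin"
        )
    return RegionPartition(
        lsc=Interval(1, irb.start - 1),
        irb=irb,
        ssc=Interval(irb.end + 1, ira.start - 1),
        ira=ira,
        total=n,
    )


# ---------------------------------------------------------------------------
# Junction spans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionSpan:
    """How far a junction-crossing gene extends into the regions on either
    side of one boundary (both spans strictly positive)."""

    gene_id: str
    junction: str
    span_upstream: int
    span_downstream: int


def junction_spans(gene: GeneAnnotation, partition: RegionPartition) -> list[JunctionSpan]:
    """Spans of *gene* across each internal junction it crosses.

    Genes wholly inside one region give an empty list.  A gene crossing
    three or more regions is rejected: plastid genes at most straddle one
    boundary, so such an annotation signals a coordinate error.
    """
    if gene.end > partition.total:
        raise PlastomeError(
            f"gene {gene.gene_id} ends at {gene.end} beyond genome length {partition.total}"
        )
    start_region = partition.region_of(gene.start)
    end_region = partition.region_of(gene.end)
    order = list(RegionPartition.REGION_NAMES)
    si, ei = order.index(start_region), order.index(end_region)
    if ei - si >= 2:
        raise PlastomeError(
            f"gene {gene.gene_id} spans {ei - si + 1} regions "
            f"({start_region}..{end_region}); check the annotation"
        )
    if si == ei:
        return []
    junction = f"{start_region}/{end_region}"
    boundary = partition.junctions[junction]
    return [
        JunctionSpan(
            gene_id=gene.gene_id,
            junction=junction,
            span_upstream=boundary - gene.start + 1,
            span_downstream=gene.end - boundary,
        )
    ]


def all_junction_spans(genes: Sequence[GeneAnnotation],
                       partition: RegionPartition) -> list[JunctionSpan]:
    spans: list[JunctionSpan] = []
    for gene in genes:
        spans.extend(junction_spans(gene, partition))
    return spans


@dataclass(frozen=True)
class JunctionShiftReport:
    """Across-species region-length ranges; ``shift = max - min`` per class.

    The IR entry is computed on the shared IR length (IRb == IRa by
    construction).
    """

    region_ranges: dict[str, tuple[int, int]]
    shifts: dict[str, int]


def junction_shift_table(partitions: Mapping[str, RegionPartition]) -> JunctionShiftReport:
    if not partitions:
        raise PlastomeError("no partitions supplied")
    lengths: dict[str, list[int]] = {"LSC": [], "IR": [], "SSC": []}
    for p in partitions.values():
        lengths["LSC"].append(len(p.lsc))
        lengths["IR"].append(len(p.irb))
        lengths["SSC"].append(len(p.ssc))
    ranges = {k: (min(v), max(v)) for k, v in lengths.items()}
    return JunctionShiftReport(
        region_ranges=ranges,
        shifts={k: mx - mn for k, (mn, mx) in ranges.items()},
    )
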