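"""Composite character-profile extraction from amplicon sequences.

An individual's barcode state at psbZ-trnfM is the joint value of four
polymorphism classes: five SNPs, a 9 bp indel, the minisatellite allele and
the C-run/A-run homopolymer.  Loci are localized in a query sequence by
15-mer anchors flanking each locus on the reference scaffold (exact match,
then a single-mismatch scan, then a global-alignment fallback); characters
are then called inside the anchored spans.  Every slot degrades to missing
independently — a truncated single read yields a partial profile, never a
failure — mirroring how incomplete Sanger reads are retained but flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from . import reference
from .errors import (
    AmbiguousAnchorError,
    HomopolymerStructureError,
    IndelLengthError,
    NovelAlleleError,
)
from .minisat import MinisatAllele, decompose
from .reference import ANCHOR_K, LOCI, ReferenceScaffold, SNP_NAMES

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class AnchorSet:
    """Upstream/downstream 15-mer anchors of each locus, read off the scaffold."""

    anchors: dict  # locus name -> (up_kmer, down_kmer)

    @classmethod
    def from_scaffold(cls, scaffold: ReferenceScaffold) -> "AnchorSet":
        seq = scaffold.sequence
        spans = reference.anchor_spans()
        anchors = {}
        for name, ((u0, u1), (d0, d1)) in spans.items():
            anchors[name] = (seq[u0:u1], seq[d0:d1])
        return cls(anchors)


def _find_anchor(seq: str, kmer: str) -> int | None:
    """Position of ``kmer`` in ``seq``: exact, then <=1-mismatch.

    Returns None when absent; raises AmbiguousAnchorError on multiple hits.
    """
    first = seq.find(kmer)
    if first != -1:
        if seq.find(kmer, first + 1) != -1:
            raise AmbiguousAnchorError(f"anchor {kmer} occurs more than once")
        return first
    hits = [
        i
        for i in range(len(seq) - len(kmer) + 1)
        if sum(a != b for a, b in zip(seq[i : i + len(kmer)], kmer)) <= 1
    ]
    if len(hits) > 1:
        raise AmbiguousAnchorError(f"anchor {kmer} matches ambiguously at {hits}")
    return hits[0] if hits else None


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -5  # the first gapped base scores -5
_aligner.extend_gap_score = -2


def global_align(a: str, b: str):
    """Optimal global alignment of two sequences.

    Scoring: match +1, mismatch -1, affine gaps with -5 for the opening
    base and -2 per extension.  Returns ``(aligned_a, aligned_b, score)``;
    among co-optimal alignments the aligner's canonical first alignment is
    returned, which is deterministic for fixed inputs.
    """
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    aln = _aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1]), aln.score


def _alignment_column_map(seq: str, scaffold: ReferenceScaffold) -> list[int | None]:
    """Map each scaffold column to the aligned query position (None at gaps)."""
    aln = _aligner.align(scaffold.sequence, seq)[0]
    colmap: list[int | None] = [None] * len(scaffold.sequence)
    t_blocks, q_blocks = aln.aligned
    for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks):
        for k in range(t1 - t0):
            colmap[t0 + k] = q0 + k
    return colmap


def _modal_offset(colmap, window) -> tuple[int, int] | None:
    """(modal query-minus-reference offset, support) over an anchor window."""
    offsets = [colmap[c] - c for c in window if colmap[c] is not None]
    if not offsets:
        return None
    counts = {}
    for o in offsets:
        counts[o] = counts.get(o, 0) + 1
    best = min(counts, key=lambda o: (-counts[o], o))
    return best, counts[best]


def _span_from_colmap(colmap, start: int, end: int) -> tuple[int, int] | None:
    """Query span between the anchor windows of a reference locus [start, end).

    Each boundary is shifted by the modal alignment offset of its anchor
    window: gaps inside a periodic repeat can be placed by the aligner a few
    columns into an anchor, so the majority offset of the window is a more
    faithful boundary than the extreme aligned column.
    """
    up = _modal_offset(colmap, range(start - ANCHOR_K, start))
    down = _modal_offset(colmap, range(end, end + ANCHOR_K))
    # require most of each anchor window to support its offset, else the
    # flank is absent (e.g. a truncated read)
    if up is None or down is None or up[1] < ANCHOR_K - 5 or down[1] < ANCHOR_K - 5:
        return None
    qs, qe = start + up[0], end + down[0]
    return (qs, qe) if qs <= qe else None


def locate_loci(
    seq: str,
    anchors: AnchorSet,
    *,
    method: str = "anchor",
    scaffold: ReferenceScaffold | None = None,
) -> dict[str, tuple[int, int] | None]:
    """Locate every locus span in ``seq``; absent loci map to None.

    ``method="anchor"`` uses direct anchor search with a global-alignment
    fallback only for loci whose anchors were not found directly;
    ``method="alignment"`` maps every locus through one global alignment
    (requires ``scaffold``).
    """
    seq = seq.upper()
    spans: dict[str, tuple[int, int] | None] = {}
    colmap = None
    for name, (up, down) in anchors.anchors.items():
        span = None
        if method == "anchor":
            u = _find_anchor(seq, up)
            d = _find_anchor(seq, down)
            if u is not None and d is not None and u + ANCHOR_K <= d:
                span = (u + ANCHOR_K, d)
        if span is None:
            if scaffold is not None:
                if colmap is None:
                    colmap = _alignment_column_map(seq, scaffold)
                span = _span_from_colmap(colmap, *LOCI[name])
        spans[name] = span
    return spans


# -- per-locus callers -------------------------------------------------------

MISSING = None


def call_snp(seq: str, span: tuple[int, int] | None):
    """Base at a located single-site span; anything but a clean A/C/G/T is missing."""
    if span is None or span[1] - span[0] != 1:
        return MISSING
    base = seq[span[0]]
    return base if base in _ACGT else MISSING


def call_deletion9(seq: str, span: tuple[int, int] | None):
    """9 bp indel state: 'absent' (segment GTACTTTAC present), 'present', or missing."""
    if span is None:
        return MISSING
    gap = span[1] - span[0]
    if gap == 0:
        return "present"
    if gap == 9:
        return "absent" if seq[span[0] : span[1]] == reference.DELETION_REF_ALLELE else MISSING
    raise IndelLengthError(gap)


def call_homopolymer(seq: str, span: tuple[int, int] | None):
    """(n_C, n_A) run lengths measured forward from the locus 5' boundary."""
    if span is None:
        return MISSING
    region = seq[span[0] : span[1]]
    if not region or region[0] != "C":
        raise HomopolymerStructureError(f"homopolymer region {region!r} does not start with C")
    n_c = len(region) - len(region.lstrip("C"))
    rest = region[n_c:]
    n_a = len(rest) - len(rest.lstrip("A"))
    if n_a == 0:
        raise HomopolymerStructureError(f"no A-run after the C-run in {region!r}")
    return (n_c, n_a)


def call_minisat(seq: str, span: tuple[int, int] | None):
    if span is None:
        return MISSING
    try:
        return decompose(seq[span[0] : span[1]])
    except NovelAlleleError:
        return MISSING


# -- composite profile -------------------------------------------------------


@dataclass(frozen=True)
class CompositeProfile:
    """The joint character state of one individual; missing slots are None."""

    snp_states: tuple  # five entries over {'A','C','G','T', None}
    deletion9: str | None  # 'present' | 'absent' | None
    minisat: MinisatAllele | None
    homopolymer: tuple | None  # (n_C, n_A) | None
    partial: bool = field(init=False)

    def __post_init__(self):
        missing = (
            any(s is None for s in self.snp_states)
            or self.deletion9 is None
            or self.minisat is None
            or self.homopolymer is None
        )
        object.__setattr__(self, "partial", missing)


def extract_profile(
    seq: str,
    scaffold: ReferenceScaffold,
    anchors: AnchorSet | None = None,
    *,
    method: str = "anchor",
) -> CompositeProfile:
    """Extract the full composite profile of an amplicon sequence.

    Slots are filled independently: a failure to locate or call one locus
    degrades that slot to missing and never fails the record.  Only
    :class:`AmbiguousAnchorError` propagates, since an ambiguous anchor
    invalidates localization as a whole.
    """
    seq = seq.upper()
    if anchors is None:
        anchors = AnchorSet.from_scaffold(scaffold)
    spans = locate_loci(seq, anchors, method=method, scaffold=scaffold)
    snps = tuple(call_snp(seq, spans[name]) for name in SNP_NAMES)

    def _soft(call, name):
        try:
            return call(seq, spans[name])
        except (IndelLengthError, HomopolymerStructureError):
            return MISSING

    return CompositeProfile(
        snp_states=snps,
        deletion9=_soft(call_deletion9, "del9"),
        minisat=call_minisat(seq, spans["minisat"]),
        homopolymer=_soft(call_homopolymer, "homopolymer"),
    )


def profile_from_row(row: reference.KeyRow) -> CompositeProfile:
    """The composite profile a character-matrix row specifies."""
    from .minisat import allele_for_haplotype

    return CompositeProfile(
        snp_states=tuple(row.snp_states),
        deletion9=row.deletion,
        minisat=allele_for_haplotype(row.minisat_haplotype),
        homopolymer=tuple(row.homopolymer),
    )
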