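"""Target-site indel calling and zygosity classification from amplicon sequences.

Mixed Sanger chromatograms are not deconvolved here: the genotyper accepts
per-allele sequences (cloned amplicons or manually resolved traces) and
classifies the plant from the resulting allele set — wild type, homozygous,
heterozygous, biallelic, or mosaic (more than two distinct alleles, the
signature of a chimeric regenerant).

Indels are normalized to their leftmost representation in reference
coordinates (VCF convention), so the same physical event always yields the
same call regardless of where the aligner opened the gap.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from Bio import Align

from ._sequence import revcomp
from .io import SequenceRecord


@dataclass
class Scoring:
    """Affine-gap global alignment scores.

    Defaults keep a 13-bp deletion as one gap (cost 6 + 13) rather than
    fragmenting it into mismatches.
    """

    match: float = 2.0
    mismatch: float = -4.0
    gap_open: float = -6.0
    gap_extend: float = -1.0


@dataclass
class Edit:
    """One aligned segment: match run, mismatch run, insertion, or deletion.

    ``ref_pos`` is 1-based: for deletions/mismatches the first affected
    reference base, for insertions the reference base the insertion follows
    (0 when inserted before the first base).
    """

    op: str  # match | mismatch | insertion | deletion
    ref_pos: int
    length: int
    sequence: str = ""


@dataclass
class AmpliconAlignment:
    ref_id: str
    query_id: str
    aligned_ref: str
    aligned_query: str
    score: float
    edits: list[Edit] = field(default_factory=list)


def expected_cut_site(amplicon_ref: SequenceRecord, guide) -> int:
    """1-based position of the reference base immediately 5' of the Cas9 cut.

    SpCas9 cuts bluntly 3 bp 5' of the PAM, i.e. between protospacer
    positions 17 and 18. The protospacer (either orientation) must occur
    exactly once in the reference.
    """
    proto = guide.protospacer if hasattr(guide, "protospacer") else str(guide)
    ref = amplicon_ref.sequence
    fwd = _find_all(ref, proto)
    rev = _find_all(ref, revcomp(proto))
    total = len(fwd) + len(rev)
    if total != 1:
        raise ValueError(
            f"protospacer occurs {total} times in {amplicon_ref.id}; need exactly one"
        )
    if fwd:
        return fwd[0] + 17  # 1-based position of protospacer base 17
    # minus strand: protospacer base p maps to plus coordinate i + (20 - p) + 1
    return rev[0] + (len(proto) - 17) + 1


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def align_to_reference(
    ref: SequenceRecord, query: SequenceRecord, scoring: Scoring | None = None
) -> AmpliconAlignment:
    """Optimal global alignment of query to reference under affine gaps."""
    if not ref.sequence or not query.sequence:
        raise ValueError("empty sequence")
    sc = scoring or Scoring()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = sc.match
    aligner.mismatch_score = sc.mismatch
    # Biopython charges open_gap_score for the first gap column and
    # extend_gap_score for each further column; a length-L gap therefore
    # costs |gap_open| + L * |gap_extend| with this mapping.
    aligner.open_gap_score = sc.gap_open + sc.gap_extend
    aligner.extend_gap_score = sc.gap_extend
    aln = aligner.align(ref.sequence, query.sequence)[0]
    a_ref, a_query = str(aln[0]), str(aln[1])
    return AmpliconAlignment(
        ref_id=ref.id, query_id=query.id,
        aligned_ref=a_ref, aligned_query=a_query, score=float(aln.score),
        edits=_edits_from_alignment(a_ref, a_query),
    )


def _edits_from_alignment(a_ref: str, a_query: str) -> list[Edit]:
    edits: list[Edit] = []
    ref_pos = 0  # 1-based position of the last consumed reference base
    i = 0
    n = len(a_ref)
    while i < n:
        r, q = a_ref[i], a_query[i]
        if r != "-" and q != "-":
            op = "match" if r == q else "mismatch"
            j = i
            seq = []
            while j < n and a_ref[j] != "-" and a_query[j] != "-" and (
                (a_ref[j] == a_query[j]) == (op == "match")
            ):
                seq.append(a_query[j])
                j += 1
            edits.append(Edit(op, ref_pos + 1, j - i, "" if op == "match" else "".join(seq)))
            ref_pos += j - i
            i = j
        elif q == "-":  # deletion from the reference
            j = i
            while j < n and a_query[j] == "-":
                j += 1
            edits.append(Edit("deletion", ref_pos + 1, j - i, a_ref[i:j]))
            ref_pos += j - i
            i = j
        else:  # insertion into the query
            j = i
            while j < n and a_ref[j] == "-":
                j += 1
            edits.append(Edit("insertion", ref_pos, j - i, a_query[i:j]))
            i = j
    return edits


def left_align_indel(edit: Edit, ref: str) -> Edit:
    """Shift an insertion/deletion to its leftmost equivalent placement."""
    if edit.op == "deletion":
        pos, seq = edit.ref_pos, edit.sequence
        # deleting ref[pos .. pos+L-1]; rotate left while the base before the
        # gap equals the last deleted base
        while pos > 1 and ref[pos - 2] == seq[-1]:
            seq = ref[pos - 2] + seq[:-1]
            pos -= 1
        return Edit("deletion", pos, edit.length, seq)
    if edit.op == "insertion":
        pos, seq = edit.ref_pos, edit.sequence
        while pos >= 1 and ref[pos - 1] == seq[-1]:
            seq = seq[-1] + seq[:-1]
            pos -= 1
        return Edit("insertion", pos, edit.length, seq)
    return edit


@dataclass
class IndelCall:
    """A normalized allele call at (or near) the target site."""

    allele_label: str
    type: str  # none | insertion | deletion | substitution | complex
    length: int
    offset_from_cut: int | None
    sequence: str
    ref_start: int = 0  # 1-based anchor (deletion start / insertion-after / first mismatch)
    details: list[Edit] = field(default_factory=list)

    def identity(self) -> tuple:
        """Key under which two calls count as the same allele."""
        return (self.type, self.length, self.sequence, self.ref_start)


WT_CALL_TYPE = "none"


def call_indel(
    alignment: AmpliconAlignment,
    cut: int | None = None,
    *,
    ref_seq: str | None = None,
    merge_gap: int = 10,
) -> IndelCall:
    """Summarize an amplicon alignment as a single allele call.

    Adjacent non-match edits separated by at most ``merge_gap`` matched bases
    merge into one cluster. One pure-deletion or pure-insertion cluster is
    left-aligned and reported with its length; pure mismatch runs are
    substitutions; anything mixed, or more than one cluster, is ``complex``
    with all edits listed.
    """
    ref = ref_seq if ref_seq is not None else alignment.aligned_ref.replace("-", "")
    variants = [e for e in alignment.edits if e.op != "match"]
    if not variants:
        return IndelCall("wt", WT_CALL_TYPE, 0, None, "", 0)

    clusters: list[list[Edit]] = [[variants[0]]]
    for e in variants[1:]:
        prev = clusters[-1][-1]
        prev_end = prev.ref_pos + (prev.length if prev.op != "insertion" else 0)
        if e.ref_pos - prev_end <= merge_gap:
            clusters[-1].append(e)
        else:
            clusters.append([e])

    def offset(pos_first: int, pos_last: int) -> int | None:
        if cut is None:
            return None
        if pos_first <= cut <= pos_last:
            return 0
        return pos_first - cut if pos_first > cut else pos_last - cut

    if len(clusters) == 1:
        cl = clusters[0]
        ops = {e.op for e in cl}
        if ops == {"deletion"} and len(cl) == 1:
            e = left_align_indel(cl[0], ref)
            return IndelCall(
                f"del{e.length}", "deletion", e.length,
                offset(e.ref_pos, e.ref_pos + e.length - 1), e.sequence, e.ref_pos, cl,
            )
        if ops == {"insertion"} and len(cl) == 1:
            e = left_align_indel(cl[0], ref)
            return IndelCall(
                f"ins{e.length}", "insertion", e.length,
                offset(e.ref_pos, e.ref_pos + 1) if cut is not None else None,
                e.sequence, e.ref_pos, cl,
            )
        if ops == {"mismatch"}:
            total = sum(e.length for e in cl)
            first, last = cl[0], cl[-1]
            return IndelCall(
                f"sub{total}", "substitution", total,
                offset(first.ref_pos, last.ref_pos + last.length - 1),
                "".join(e.sequence for e in cl), first.ref_pos, cl,
            )
    all_edits = [e for cl in clusters for e in cl]
    span = sum(e.length for e in all_edits)
    first, last = all_edits[0], all_edits[-1]
    return IndelCall(
        f"complex{span}", "complex", span,
        offset(first.ref_pos, max(last.ref_pos + last.length - 1, first.ref_pos)),
        "", first.ref_pos, all_edits,
    )


def apply_indel(ref: str, call: IndelCall) -> str:
    """Reconstruct the query implied by a non-complex call (round-trip check)."""
    if call.type == WT_CALL_TYPE:
        return ref
    p = call.ref_start
    if call.type == "deletion":
        return ref[: p - 1] + ref[p - 1 + call.length :]
    if call.type == "insertion":
        return ref[:p] + call.sequence + ref[p:]
    if call.type == "substitution":
        out = list(ref)
        i = 0
        for e in call.details:
            out[e.ref_pos - 1 : e.ref_pos - 1 + e.length] = e.sequence
            i += e.length
        return "".join(out)
    raise ValueError("cannot reconstruct a complex call")


@dataclass
class ZygosityCall:
    plant_id: str
    genotype: str  # wild_type | homozygous | heterozygous | biallelic | mosaic
    alleles: list[tuple[IndelCall, int]]  # distinct calls with supporting counts


def classify_zygosity(plant_id: str, allele_calls: list[IndelCall]) -> ZygosityCall:
    """Classify a plant from its set of resolved allele calls.

    Two calls are the same allele when type, length, sequence and anchor all
    agree. More than two distinct alleles (wild type included) is a mosaic —
    a diploid cannot carry three alleles in one cell lineage.
    """
    if not allele_calls:
        raise ValueError("need at least one allele call")
    counter: Counter[tuple] = Counter(c.identity() for c in allele_calls)
    by_key = {c.identity(): c for c in allele_calls}
    distinct = list(counter)
    non_wt = [k for k in distinct if k[0] != WT_CALL_TYPE]
    has_wt = len(non_wt) < len(distinct)

    if not non_wt:
        genotype = "wild_type"
    elif len(distinct) > 2:
        genotype = "mosaic"
    elif len(non_wt) == 1:
        genotype = "heterozygous" if has_wt else "homozygous"
    else:
        genotype = "biallelic"
    alleles = [(by_key[k], counter[k]) for k in distinct]
    return ZygosityCall(plant_id=plant_id, genotype=genotype, alleles=alleles)


@dataclass
class SiteVerdict:
    site_id: str
    clean: bool
    call: IndelCall


def verify_offtarget_amplicons(
    pairs: list[tuple[SequenceRecord, SequenceRecord]],
    *,
    max_substitutions: int = 0,
) -> list[SiteVerdict]:
    """Check candidate off-target sites for mutations, cut-agnostically.

    Each (reference amplicon, sample amplicon) pair is aligned and called
    with no cut-site requirement; a site is clean when the call is wild type,
    or a substitution of at most ``max_substitutions`` bases (sequencing
    noise tolerance, default none).
    """
    verdicts = []
    for ref, qry in pairs:
        call = call_indel(align_to_reference(ref, qry), cut=None, ref_seq=ref.sequence)
        clean = call.type == WT_CALL_TYPE or (
            call.type == "substitution" and call.length <= max_substitutions
        )
        verdicts.append(SiteVerdict(site_id=ref.id, clean=clean, call=call))
    return verdicts


def summarize_verdicts(verdicts: list[SiteVerdict]) -> str:
    n_mut = sum(not v.clean for v in verdicts)
    return f"{n_mut}/{len(verdicts)} mutated"
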