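"""Exhaustive mismatch-tolerant scan for Cas9 guide matches in a genome.

Every window on either strand whose 3-nt PAM position matches the IUPAC PAM
pattern and whose 20-nt protospacer-equivalent lies within a Hamming-distance
budget of the guide is reported. Unlike a heuristic BLAST search, the scan is
exhaustive: no qualifying site can be missed.

Mismatches are counted over the protospacer only; the PAM must satisfy its
IUPAC pattern (N matches anything). A genomic ambiguity code matches a guide
base when the base is contained in the code's set, and a PAM pattern
character when their sets intersect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._sequence import IUPAC_SETS, revcomp, validate_dna
from .io import SequenceRecord

logger = logging.getLogger(__name__)

PROTOSPACER_LEN = 20
PAM_LEN = 3

# char-code -> index into the 15-letter IUPAC table; 255 = not a DNA letter
_IUPAC_ORDER = "ACGTRYSWKMBDHVN"
_CODE_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(_IUPAC_ORDER):
    _CODE_IDX[ord(_c)] = _i
    _CODE_IDX[ord(_c.lower())] = _i

# _INTERSECTS[i, j]: do the base sets of IUPAC letters i and j intersect?
_INTERSECTS = np.zeros((16, 16), dtype=bool)
for _i, _a in enumerate(_IUPAC_ORDER):
    for _j, _b in enumerate(_IUPAC_ORDER):
        _INTERSECTS[_i, _j] = bool(IUPAC_SETS[_a] & IUPAC_SETS[_b])

# _CONTAINS[i, j]: does the set of genome letter i contain concrete base j (ACGT)?
_CONTAINS = np.zeros((16, 4), dtype=bool)
for _i, _a in enumerate(_IUPAC_ORDER):
    for _j, _b in enumerate("ACGT"):
        _CONTAINS[_i, _j] = _b in IUPAC_SETS[_a]


@dataclass
class GuideSite:
    """A 20-nt protospacer plus its PAM requirement (default SpCas9 NGG)."""

    protospacer: str
    pam_pattern: str = "NGG"

    def __post_init__(self) -> None:
        self.protospacer = validate_dna(self.protospacer, name="protospacer")
        self.pam_pattern = validate_dna(self.pam_pattern, name="pam_pattern")
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError(f"protospacer must be {PROTOSPACER_LEN} nt")
        if len(self.pam_pattern) != PAM_LEN:
            raise ValueError(f"PAM pattern must be {PAM_LEN} nt")
        if set(self.protospacer) - set("ACGT"):
            raise ValueError("protospacer must be concrete ACGT")

    @property
    def combined_query(self) -> str:
        """Protospacer + PAM, 23 nt."""
        return self.protospacer + self.pam_pattern


@dataclass
class OffTargetHit:
    """One genomic site matching the guide within the mismatch budget.

    ``start`` is the 1-based plus-strand coordinate of the 5'-most base of
    the protospacer-equivalent 20-mer; ``site_sequence`` is the 23-nt
    protospacer+PAM read in guide orientation.
    """

    seq_id: str
    start: int
    strand: str
    mismatches: int
    site_sequence: str
    is_on_target: bool

    @property
    def end(self) -> int:
        return self.start + PROTOSPACER_LEN - 1


def _scan_one_strand(
    idxs: np.ndarray, guide: GuideSite, strand: str, max_mismatches: int
) -> tuple[np.ndarray, np.ndarray]:
    """Window starts (0-based, full 23-nt window) and mismatch counts, one strand.

    On '+', the window is protospacer(20) + PAM(3); on '-', the plus-strand
    layout is revcomp(PAM)(3) + revcomp(protospacer)(20).
    """
    w = PROTOSPACER_LEN + PAM_LEN
    n = idxs.size - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    if strand == "+":
        proto = guide.protospacer
        pam = guide.pam_pattern
        proto_off = 0
        pam_off = PROTOSPACER_LEN
    else:
        proto = revcomp(guide.protospacer)
        pam = revcomp(guide.pam_pattern)
        proto_off = PAM_LEN
        pam_off = 0

    mm = np.zeros(n, dtype=np.int16)
    for j, base in enumerate(proto):
        col = idxs[proto_off + j : proto_off + j + n]
        mm += ~_CONTAINS[col, "ACGT".index(base)]
    pam_ok = np.ones(n, dtype=bool)
    for j, pchar in enumerate(pam):
        col = idxs[pam_off + j : pam_off + j + n]
        pam_ok &= _INTERSECTS[col, _CODE_IDX[ord(pchar)]]
    keep = pam_ok & (mm <= max_mismatches)
    return np.flatnonzero(keep).astype(np.int64), mm[keep].astype(np.int64)


def find_offtarget_sites(
    genome: list[SequenceRecord],
    guide: GuideSite,
    max_mismatches: int = 3,
) -> list[OffTargetHit]:
    """All PAM-anchored matches of the guide within the mismatch budget.

    Scans both strands of every record; results are sorted by
    (seq_id, start, strand). Perfect protospacer matches are flagged
    ``is_on_target``. Records shorter than 23 nt are skipped with a warning.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    if not genome:
        raise ValueError("genome is empty")
    w = PROTOSPACER_LEN + PAM_LEN
    hits: list[OffTargetHit] = []
    for rec in genome:
        if len(rec.sequence) < w:
            logger.warning("record %s shorter than %d nt; skipped", rec.id, w)
            continue
        idxs = _CODE_IDX[np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8)]
        for strand in "+-":
            starts, mms = _scan_one_strand(idxs, guide, strand, max_mismatches)
            for s0, mm in zip(starts.tolist(), mms.tolist()):
                window = rec.sequence[s0 : s0 + w]
                if strand == "+":
                    start = s0 + 1
                    site = window
                else:
                    start = s0 + PAM_LEN + 1
                    site = revcomp(window)
                hits.append(
                    OffTargetHit(
                        seq_id=rec.id, start=start, strand=strand,
                        mismatches=mm, site_sequence=site, is_on_target=(mm == 0),
                    )
                )
    hits.sort(key=lambda h: (h.seq_id, h.start, h.strand))
    return hits


def site_report(
    hits: list[OffTargetHit],
    genome: list[SequenceRecord] | None = None,
    *,
    flank: int = 200,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate hits and per-sequence tallies.

    Returns ``(per_hit, tally)`` DataFrames. With ``genome`` given, each hit
    row carries +/- ``flank`` bp of plus-strand context for downstream primer
    design. Duplicate (seq_id, start, strand) entries are collapsed.
    """
    cols = ["seq_id", "start", "end", "strand", "mismatches", "site_sequence", "on_target"]
    rows = []
    seen = set()
    seqs = {r.id: r.sequence for r in genome} if genome else {}
    for h in hits:
        key = (h.seq_id, h.start, h.strand)
        if key in seen:
            continue
        seen.add(key)
        row = {
            "seq_id": h.seq_id, "start": h.start, "end": h.end, "strand": h.strand,
            "mismatches": h.mismatches, "site_sequence": h.site_sequence,
            "on_target": h.is_on_target,
        }
        if h.seq_id in seqs:
            s = seqs[h.seq_id]
            row["context"] = s[max(h.start - 1 - flank, 0) : min(h.end + flank, len(s))]
        rows.append(row)
    per_hit = pd.DataFrame(rows, columns=cols + (["context"] if genome else []))
    if per_hit.empty:
        tally = pd.DataFrame(columns=["seq_id", "n_hits"])
    else:
        tally = (
            per_hit.groupby("seq_id", as_index=False).size().rename(columns={"size": "n_hits"})
        )
    return per_hit, tally
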