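"""Synthetic data with the structure the screening analysis assumes.

The generator emulates, at reduced scale, a plant transformation experiment:

* a host genome (default 1 Mb standing in for a multi-gigabase cereal
  genome — the screen's statistics are depth-normalized, so conclusions
  transfer);
* a binary-vector construct (default 19,074 bp, T-DNA spanning 1–12,584)
  that carries (a) a segment copied from the host, emulating a host-derived
  promoter that legitimately attracts host reads in every sample, and (b) a
  low-complexity C-rich 21-bp tract that also occurs repeatedly in the host
  genome, emulating the classic false-positive region of k-mer screens;
* an editing outcome: no insertion, a full T-DNA insertion, or short
  (20–21 bp) residual construct fragments at random loci;
* uniformly placed sequencing reads with substitution errors.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._sequence import decode, encode
from .io import ConstructAnnotation, SequenceRecord

#: C-rich low-complexity decoy tract (21 bp) placed in the T-DNA and planted
#: repeatedly in the host genome.
DECOY_SEQ = "CCTCCCCCCCCCCCCCTCTCT"

DEFAULT_CONSTRUCT_LENGTH = 19_074
DEFAULT_TDNA_END = 12_584
DEFAULT_DECOY_START = 2_069


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic screening experiment.

    Defaults mirror the study conditions the package is designed around:
    construct 19,074 bp with T-DNA 1–12,584, C-rich decoy at 2,069–2,089,
    150-bp reads at ~30x depth with 0.5% substitution error.
    """

    seed: int = 0
    host_length: int = 1_000_000
    gc: float = 0.44
    construct_length: int = DEFAULT_CONSTRUCT_LENGTH
    tdna_end: int = DEFAULT_TDNA_END
    homology_length: int = 2_000
    homology_start: int = 3_001  # construct coordinate, inside the T-DNA
    decoy_start: int = DEFAULT_DECOY_START
    decoy_host_copies: int = 25
    event: str = "none"  # none | full_insertion | fragment
    fragment_lengths: list[int] = field(default_factory=lambda: [20, 21])
    depth: float = 30.0
    read_length: int = 150
    error_rate: float = 0.005

    def __post_init__(self) -> None:
        if not 0 < self.tdna_end < self.construct_length:
            raise ValueError("tdna_end must lie inside the construct")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.event not in ("none", "full_insertion", "fragment"):
            raise ValueError(f"unknown event {self.event!r}")
        h0, h1 = self.homology_start, self.homology_start + self.homology_length - 1
        d0, d1 = self.decoy_start, self.decoy_start + len(DECOY_SEQ) - 1
        if h1 > self.tdna_end or d1 > self.tdna_end:
            raise ValueError("homology segment and decoy must lie inside the T-DNA")
        if not (h1 < d0 or d1 < h0):
            raise ValueError("homology segment and decoy placements overlap")


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    edges = np.cumsum(p)[:-1]
    return np.searchsorted(edges, rng.random(length), side="right").astype(np.uint8)


def generate_host_genome(length: int, gc: float, seed: int) -> SequenceRecord:
    """Reproducible pseudo-random host chromosome at the requested GC."""
    if length < 10_000:
        raise ValueError("host genome must be at least 10 kb for screening scenarios")
    rng = np.random.default_rng(seed)
    return SequenceRecord("host_chr1", decode(_random_dna(rng, length, gc)))


def generate_construct(
    host: SequenceRecord, scenario: SyntheticScenario, *, rng: np.random.Generator | None = None
) -> tuple[SequenceRecord, ConstructAnnotation, dict]:
    """Build the transformation construct and its annotation.

    The construct is random sequence except for two embedded segments: a
    host-homologous block copied from the host (inside the T-DNA) and the
    C-rich decoy tract. Marker features HPT and Cas9 are annotated inside
    the T-DNA, clear of both segments. Returns (construct, annotation,
    placement-truth dict).
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed + 1) if rng is None else rng
    if len(host) < sc.homology_length + 10_000:
        raise ValueError("host too short to donate the homology segment")
    arr = _random_dna(rng, sc.construct_length, sc.gc)

    hom_src = int(rng.integers(0, len(host) - sc.homology_length))
    h0 = sc.homology_start - 1
    if sc.homology_length:
        arr[h0 : h0 + sc.homology_length] = encode(
            host.sequence[hom_src : hom_src + sc.homology_length]
        )
    d0 = sc.decoy_start - 1
    arr[d0 : d0 + len(DECOY_SEQ)] = encode(DECOY_SEQ)

    # marker features sit in the T-DNA at fixed fractions, clear of the
    # homology segment and the decoy by construction of the defaults
    features = {
        "HPT": (int(0.45 * sc.tdna_end) + 1, int(0.55 * sc.tdna_end)),
        "Cas9": (int(0.60 * sc.tdna_end) + 1, int(0.93 * sc.tdna_end)),
        "homology_segment": (sc.homology_start, sc.homology_start + sc.homology_length - 1),
        "decoy": (sc.decoy_start, sc.decoy_start + len(DECOY_SEQ) - 1),
    }
    ivs = sorted(features.values())
    for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
        if b0 <= a1:
            raise ValueError(
                f"overlapping construct placements: ({a0},{a1}) and ({b0},{b1})"
            )
    construct = SequenceRecord("construct", decode(arr))
    annotation = ConstructAnnotation(
        construct_id="construct",
        length=sc.construct_length,
        tdna_interval=(1, sc.tdna_end),
        features=features,
    )
    truth = {"homology_source_start": hom_src + 1}
    return construct, annotation, truth


def plant_decoy_copies(
    host: SequenceRecord, n_copies: int, rng: np.random.Generator
) -> SequenceRecord:
    """Overwrite ``n_copies`` random non-overlapping host loci with the decoy tract."""
    arr = encode(host.sequence).copy()
    L = len(DECOY_SEQ)
    taken: list[int] = []
    dec = encode(DECOY_SEQ)
    while len(taken) < n_copies:
        s = int(rng.integers(0, arr.size - L))
        if all(abs(s - t) >= L for t in taken):
            arr[s : s + L] = dec
            taken.append(s)
    return SequenceRecord(host.id, decode(arr))


def apply_event(
    host: SequenceRecord,
    construct: SequenceRecord,
    annotation: ConstructAnnotation,
    scenario: SyntheticScenario,
    *,
    rng: np.random.Generator | None = None,
) -> tuple[SequenceRecord, dict]:
    """Apply the editing outcome to the host genome.

    ``none`` leaves the host unchanged; ``full_insertion`` inserts the whole
    T-DNA at a random locus; ``fragment`` inserts, for each requested length,
    one T-DNA substring at a random host locus. Fragment sources avoid the
    host-homologous block and the decoy (a fragment drawn from those would be
    indistinguishable from background) and each other. Returns the edited
    genome and a truth dict with the planted coordinates.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed + 2) if rng is None else rng
    harr = encode(host.sequence)
    carr = encode(construct.sequence)
    tdna = carr[: sc.tdna_end]
    truth: dict = {"event": sc.event}

    if sc.event == "none":
        return SequenceRecord("edited_genome", host.sequence), truth

    if sc.event == "full_insertion":
        locus = int(rng.integers(0, harr.size))
        edited = np.concatenate([harr[:locus], tdna, harr[locus:]])
        truth["insertion_locus"] = locus + 1
        return SequenceRecord("edited_genome", decode(edited)), truth

    # fragments
    k_guard = 25
    blocked: list[tuple[int, int]] = [
        (sc.homology_start - k_guard, sc.homology_start + sc.homology_length + k_guard),
        (sc.decoy_start - k_guard, sc.decoy_start + len(DECOY_SEQ) + k_guard),
    ]
    sources = []
    for ln in sc.fragment_lengths:
        if ln < 8:
            raise ValueError(f"fragment length {ln} shorter than any usable k")
        while True:
            s = int(rng.integers(1, sc.tdna_end - ln + 1))
            span = (s - k_guard, s + ln + k_guard)
            if all(span[1] <= b0 or span[0] >= b1 for b0, b1 in blocked):
                blocked.append(span)
                sources.append((s, ln))
                break
    placements = []
    for s, ln in sources:
        # force the junction bases to break homology with the construct, so a
        # planted f-bp fragment matches the construct over exactly f bases
        left_c = carr[s - 2] if s >= 2 else -1
        right_c = carr[s - 1 + ln] if s - 1 + ln < carr.size else -1
        while True:
            locus = int(rng.integers(1, harr.size - 1))
            if harr[locus - 1] != left_c and harr[locus] != right_c:
                placements.append((locus, s, ln))
                break
    placements.sort()
    pieces = []
    cursor = 0
    frag_truth = []
    for locus, s, ln in placements:
        pieces.append(harr[cursor:locus])
        pieces.append(carr[s - 1 : s - 1 + ln])
        frag_truth.append({"construct_start": s, "length": ln, "host_locus": locus + 1})
        cursor = locus
    pieces.append(harr[cursor:])
    truth["fragments"] = sorted(frag_truth, key=lambda d: d["construct_start"])
    return SequenceRecord("edited_genome", decode(np.concatenate(pieces))), truth


def simulate_reads(
    genome: SequenceRecord,
    depth: float,
    read_length: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
    *,
    sample_id: str = "sim",
) -> list[SequenceRecord]:
    """Uniformly placed reads from both strands with substitution errors.

    Read count is ``round(depth * genome_length / read_length)``; each read
    starts uniformly, takes either strand with probability 1/2, and each base
    substitutes to a uniformly chosen different base with ``error_rate``.
    Deterministic under the seed.
    """
    rng = np.random.default_rng(seed)
    L = len(genome)
    n = int(round(depth * L / read_length))
    if n < 1:
        raise ValueError("depth * genome_length must yield at least one read")
    enc = encode(genome.sequence)
    starts = rng.integers(0, L - read_length + 1, size=n)
    mat = enc[starts[:, None] + np.arange(read_length)[None, :]]
    minus = rng.random(n) < 0.5
    mat[minus] = (3 - mat[minus])[:, ::-1]
    if error_rate > 0:
        err = rng.random((n, read_length)) < error_rate
        shift = rng.integers(1, 4, size=(n, read_length), dtype=np.uint8)
        mat = np.where(err, (mat + shift) % 4, mat)
    qual = [40] * read_length
    return [
        SequenceRecord(f"{sample_id}_{i:07d}", decode(mat[i]), list(qual)) for i in range(n)
    ]


def generate_amplicons(
    ref_region: SequenceRecord, alleles: list[dict], seed: int = 0
) -> list[SequenceRecord]:
    """Build per-allele amplicon sequences from edit specifications.

    Each allele spec is a dict: ``label``; ``type`` in none/deletion/
    insertion; for deletions ``position`` (1-based first deleted base) and
    ``length``; for insertions ``position`` (1-based base the insert
    follows) and ``sequence``.
    """
    ref = ref_region.sequence
    out = []
    for spec in alleles:
        typ = spec.get("type", "none")
        label = spec.get("label", typ)
        if typ == "none":
            seq = ref
        elif typ == "deletion":
            p, ln = spec["position"], spec["length"]
            if not (1 <= p and p + ln - 1 <= len(ref)):
                raise ValueError(f"{label}: deletion outside region")
            seq = ref[: p - 1] + ref[p - 1 + ln :]
        elif typ == "insertion":
            p, ins = spec["position"], spec["sequence"]
            if not 0 <= p <= len(ref):
                raise ValueError(f"{label}: insertion point outside region")
            seq = ref[:p] + ins + ref[p:]
        else:
            raise ValueError(f"{label}: unknown allele type {typ!r}")
        out.append(SequenceRecord(f"{ref_region.id}|{label}", seq))
    return out


def generate_trait_data(groups: list[tuple[str, int, float, float]], seed: int = 0) -> pd.DataFrame:
    """Normal per-individual draws for each (label, n, mean, sd) group."""
    rng = np.random.default_rng(seed)
    rows = []
    for label, n, mean, sd in groups:
        if n < 2:
            raise ValueError(f"{label}: need n >= 2")
        if sd <= 0:
            raise ValueError(f"{label}: sd must be positive")
        for v in rng.normal(mean, sd, size=n):
            rows.append({"label": label, "value": float(v)})
    return pd.DataFrame(rows)


@dataclass
class ScenarioData:
    """All artifacts of one built scenario."""

    scenario: SyntheticScenario
    host: SequenceRecord  # wild-type genome (decoy copies planted)
    construct: SequenceRecord
    annotation: ConstructAnnotation
    edited: SequenceRecord
    truth: dict


def build_scenario(scenario: SyntheticScenario) -> ScenarioData:
    """Generate host, construct and edited genome for a scenario.

    The decoy copies are planted in the host *before* the homology segment is
    drawn (from a decoy-free window check this is unnecessary at these
    scales; collisions are vanishingly unlikely and harmless).
    """
    sc = scenario
    host0 = generate_host_genome(sc.host_length, sc.gc, sc.seed)
    rng = np.random.default_rng(sc.seed + 7)
    host = plant_decoy_copies(host0, sc.decoy_host_copies, rng)
    construct, annotation, truth_c = generate_construct(host, sc, rng=rng)
    edited, truth_e = apply_event(host, construct, annotation, sc, rng=rng)
    truth = {**truth_c, **truth_e, "seed": sc.seed}
    return ScenarioData(sc, host, construct, annotation, edited, truth)


def scenario_reads(
    data: ScenarioData, *, which: str, seed_offset: int = 0
) -> list[SequenceRecord]:
    """Simulate reads for the control (wild-type host) or the edited sample."""
    sc = data.scenario
    genome = data.host if which == "control" else data.edited
    return simulate_reads(
        genome, sc.depth, sc.read_length, sc.error_rate,
        seed=sc.seed + 101 + seed_offset + (0 if which == "control" else 50_000),
        sample_id=which,
    )


def screen_scenario(scenario: SyntheticScenario, *, k: int = 20, alpha: float = 0.01):
    """Build a scenario and run the full k-mer screen on it.

    Returns ``(scenario_data, screen_result)``; the negative control is the
    wild-type host read set, the query the edited-genome read set.
    """
    from .kmer import build_kmer_index, count_read_kmers, screen_sample

    data = build_scenario(scenario)
    index = build_kmer_index(data.construct, k)
    control = count_read_kmers(
        scenario_reads(data, which="control"), index, sample_id="wild_type"
    )
    result = screen_sample(
        index, data.annotation, control, scenario_reads(data, which="sample"),
        sample_id=f"{scenario.event}_{scenario.seed}", alpha=alpha,
    )
    return data, result


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, default=str) + "\n")


def scenario_from_dict(cfg: dict) -> SyntheticScenario:
    known = {f for f in SyntheticScenario.__dataclass_fields__}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    return SyntheticScenario(**cfg)


def scenario_to_dict(sc: SyntheticScenario) -> dict:
    return asdict(sc)
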