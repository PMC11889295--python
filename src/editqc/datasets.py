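"""Small bundled datasets: published-style trait summaries and the guide.

These are desk-scale fixtures for worked examples and for reproducing the
trait statistics without any external downloads: the agronomic trait
summaries (culm length, thousand-grain weight, hectoliter grain weight) and
germination-test summaries for wild-type barley DH120366 and the two nud
mutant lines, and the sgRNA8 guide targeting NUD with its 43-nt amplicon
context.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .io import SequenceRecord
from .offtarget import GuideSite
from .traits import GroupSummary


def _data_path(name: str):
    return resources.files("editqc.data").joinpath(name)


def load_trait_summaries() -> pd.DataFrame:
    """Trait summary table: trait, label, n, mean, sd (one row per group)."""
    with resources.as_file(_data_path("nud_trait_summaries.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_germination_summaries() -> pd.DataFrame:
    """Germination-rate summary table for both trials (proportions)."""
    with resources.as_file(_data_path("nud_germination.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def trait_groups(df: pd.DataFrame, trait: str) -> list[GroupSummary]:
    sub = df[df["trait"] == trait]
    if sub.empty:
        raise KeyError(f"no rows for trait {trait!r}")
    return [
        GroupSummary(r.label, int(r.n), float(r.mean), float(r.sd))
        for r in sub.itertuples()
    ]


def load_guide() -> dict:
    """Guide metadata: protospacer, PAM pattern, amplicon context."""
    return json.loads(_data_path("nud_guide.json").read_text())


def nud_guide_site() -> GuideSite:
    g = load_guide()
    return GuideSite(g["protospacer"], g["pam_pattern"])


def nud_amplicon_context() -> SequenceRecord:
    g = load_guide()
    return SequenceRecord("NUD_context", g["amplicon_context"])


def default_scenario_yaml() -> str:
    return _data_path("default_scenario.yaml").read_text()
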