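"""Core domain records shared across the pipeline.

A :class:`GenomeRecord` is a MAG (metagenome-assembled genome) or a labeled
training genome: an ordered set of contigs plus the external quality metrics
(completeness %, contamination %, N50) that a tool such as CheckM would
report.  A :class:`PathwayCatalog` names the fermentation pathways of
interest and, for each, a roster of protein query sequences used for
translated homology search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

GROUPS = (
    "ferment_to_intermediates",
    "intermediate_ce",
    "carbohydrate_ce",
    "uninvolved",
)

DEFAULT_PATHWAYS = (
    "homolactic",
    "phosphoketolase",
    "bifid_shunt",
    "lactic_acid_utilization",
    "reverse_beta_oxidation",
)


@dataclass(frozen=True)
class EnzymeEntry:
    """One protein query in a pathway roster."""

    enzyme: str
    pathway: str
    sequence: str
    is_unique: bool = True  # occurs in exactly one pathway roster


@dataclass
class PathwayCatalog:
    """Named pathways, each a roster of enzyme queries.

    ``extras`` holds companion proteins that are searched for but are not
    roster members (e.g. the ACD-partnered EtfB used for the electron
    transfer flavoprotein analysis).
    """

    pathways: dict[str, list[EnzymeEntry]]
    extras: dict[str, str] = field(default_factory=dict)

    @property
    def pathway_names(self) -> list[str]:
        return list(self.pathways)

    @property
    def enzymes(self) -> list[EnzymeEntry]:
        return [e for roster in self.pathways.values() for e in roster]

    @property
    def enzyme_names(self) -> list[str]:
        return [e.enzyme for e in self.enzymes]

    def roster(self, pathway: str) -> list[EnzymeEntry]:
        return self.pathways[pathway]

    def get_enzyme(self, name: str) -> EnzymeEntry:
        for e in self.enzymes:
            if e.enzyme == name:
                return e
        raise KeyError(f"unknown enzyme query: {name!r}")

    def mark_unique(self) -> None:
        """Recompute ``is_unique`` flags: an enzyme name appearing in more
        than one pathway roster is not unique to any of them."""
        counts: dict[str, int] = {}
        for e in self.enzymes:
            counts[e.enzyme] = counts.get(e.enzyme, 0) + 1
        for pw, roster in self.pathways.items():
            self.pathways[pw] = [
                EnzymeEntry(e.enzyme, e.pathway, e.sequence, counts[e.enzyme] == 1)
                for e in roster
            ]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"pathway": e.pathway, "enzyme": e.enzyme, "is_unique": int(e.is_unique)}
            for e in self.enzymes
        ]
        return pd.DataFrame(rows, columns=["pathway", "enzyme", "is_unique"])


@dataclass
class GenomeRecord:
    """A genome: contigs plus externally supplied quality metrics."""

    genome_id: str
    contigs: dict[str, str]
    completeness: float = 100.0  # percent
    contamination: float = 0.0  # percent
    n50: int = 1

    @property
    def size(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def sequence(self) -> str:
        """All contigs concatenated (sketching convenience)."""
        return "".join(self.contigs.values())


def quality_frame(genomes: list[GenomeRecord]) -> pd.DataFrame:
    """Quality table with the columns dereplication consumes."""
    return pd.DataFrame(
        {
            "genome_id": [g.genome_id for g in genomes],
            "completeness": [g.completeness for g in genomes],
            "contamination": [g.contamination for g in genomes],
            "N50": [g.n50 for g in genomes],
            "size": [g.size for g in genomes],
        }
    )
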