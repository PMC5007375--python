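"""The paired-lineage comparative design.

The analyses in this package all hinge on a simple comparative skeleton: an
outgroup/reference species plus an ordered list of (mutualist, generalist)
sister-lineage pairs.  Pairing the most closely related mutualist and
generalist lineages cancels shared evolutionary history, so that per-unit
(gene or window) contrasts isolate the life-history effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class PairDesign:
    """Outgroup label plus ordered (mutualist, generalist) pairs.

    Parameters
    ----------
    outgroup : str
        Label of the reference species all distances are measured against.
    pairs : tuple of (str, str)
        Ordered (mutualist, generalist) sister-pair labels.
    """

    outgroup: str = "gracilis"
    pairs: tuple[tuple[str, str], ...] = (
        ("concolor", "pallidus"),
        ("flavicornis", "PSW54"),
        ("dendroicus", "elongatus"),
    )

    def __post_init__(self) -> None:
        labels = self.all_species
        if len(set(labels)) != len(labels):
            raise ValueError("species labels in the design must be distinct")

    @property
    def mutualists(self) -> list[str]:
        return [m for m, _ in self.pairs]

    @property
    def generalists(self) -> list[str]:
        return [g for _, g in self.pairs]

    @property
    def ingroup(self) -> list[str]:
        return [s for pair in self.pairs for s in pair]

    @property
    def all_species(self) -> list[str]:
        return [self.outgroup] + self.ingroup

    def validate_against(self, species: list[str] | set[str]) -> None:
        """Raise ValueError naming any design label absent from *species*."""
        missing = [s for s in self.all_species if s not in set(species)]
        if missing:
            raise ValueError(f"design species absent from data: {missing}")


#: Default seven-taxon topology: the outgroup, then one mutualist/generalist
#: pair nested per clade, with the pallidus lineage sister to the
#: (flavicornis, PSW54) clade.  Root-to-tip depth is 0.025 expected
#: substitutions/site, i.e. ~5% pairwise divergence from the outgroup.
DEFAULT_NEWICK = (
    "(gracilis:0.025,(concolor:0.02,((dendroicus:0.007,elongatus:0.007):0.008,"
    "(pallidus:0.01,(flavicornis:0.005,PSW54:0.005):0.005):0.005):0.005):0.005);"
)

DEFAULT_DESIGN = PairDesign()
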