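"""Signature reversal: which disease genes does a drug oppositely regulate?

The comparison stage of the method: the disease signature (Set A,
significant genes with up/down directions) is intersected with each
drug-treatment signature (Set B), keeping only the genes whose direction
flips — up in disease and down after treatment, or vice versa. Such a
gene is a probable target of the drug.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = ["DrugTargetSet", "opposite_regulation", "restrict_to_drug_affected"]


@dataclass
class DrugTargetSet:
    """Genes of one disease whose regulation one drug makes opposite.

    ``targets`` maps gene → (disease_direction, drug_direction); the two
    directions differ for every stored gene, and every stored gene is
    significant in both contrasts by construction.
    """

    disease_id: str
    drug_id: str
    targets: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for gene, (d_dis, d_drug) in self.targets.items():
            if d_dis == d_drug:
                raise ValueError(f"{gene}: directions must differ ({d_dis!r})")

    def genes(self) -> set[str]:
        return set(self.targets)

    def __len__(self) -> int:
        return len(self.targets)


def opposite_regulation(
    set_a: Mapping[str, str],
    set_b: Mapping[str, str],
    *,
    disease_id: str = "",
    drug_id: str = "",
) -> DrugTargetSet:
    """Intersect a disease and a drug signature, keeping discordant genes.

    ``set_a`` / ``set_b`` map gene → direction ("up"/"down") for the
    disease and drug contrasts respectively. An empty result is allowed.
    """
    targets = {
        gene: (set_a[gene], set_b[gene])
        for gene in set(set_a) & set(set_b)
        if set_a[gene] != set_b[gene]
    }
    return DrugTargetSet(disease_id=disease_id, drug_id=drug_id, targets=targets)


def restrict_to_drug_affected(
    disease_genes: Iterable[str], target_sets: Iterable[DrugTargetSet]
) -> set[str]:
    """Disease genes up/down-regulated under at least one drug in the panel.

    This is the optional pre-network restriction: only disease genes
    appearing in some drug's target set are carried forward. An empty
    drug panel yields the empty set.
    """
    affected: set[str] = set()
    for ts in target_sets:
        affected |= ts.genes()
    return set(disease_genes) & affected
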