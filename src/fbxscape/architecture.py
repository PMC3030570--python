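"""C-terminal recruitment-module architectures and per-species enrichment.

An FBX protein's architecture is the ordered list of module hits C-terminal
to its F-box domain ("FBXD" alone when none are found).  Architectures with
at least 10 members across the collection are "frequent"; per-species
enrichment/depletion is a one-sided Fisher exact test of each species
against all remaining species pooled (p < 0.05, no multiple-testing
correction by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .search import DomainModel, pssm_scan
from .stats import fisher_exact_one_sided

FREQUENT_MIN_MEMBERS = 10


@dataclass(frozen=True)
class Architecture:
    modules: tuple[str, ...]  # ordered, FBXD first

    def __post_init__(self) -> None:
        if not self.modules or self.modules[0] != "FBXD":
            raise ValueError("architecture must start with FBXD")

    @property
    def canonical(self) -> str:
        return "+".join(self.modules)


@dataclass
class ArchitectureGroup:
    architecture: str
    members: list[str]
    frequency_class: str = ""

    def __post_init__(self) -> None:
        if not self.frequency_class:
            if len(self.members) >= FREQUENT_MIN_MEMBERS:
                self.frequency_class = "frequent"
            elif len(self.members) > 1:
                self.frequency_class = "rare"
            else:
                self.frequency_class = "none"


def assign_modules(
    protein: str,
    fbxd_model: DomainModel,
    module_models: Mapping[str, DomainModel],
) -> Architecture:
    """Ordered non-overlapping best-scoring modules C-terminal to the FBXD."""
    fbxd_hits = pssm_scan(protein, fbxd_model)
    if not fbxd_hits:
        raise ValueError("no FBXD detected: not an FBX protein")
    fbxd_end = fbxd_hits[0].end
    hits = []
    for name, model in sorted(module_models.items()):
        for h in pssm_scan(protein, model):
            if h.start >= fbxd_end:
                hits.append(h)
    hits.sort(key=lambda h: (-h.score, h.start))
    chosen = []
    for h in hits:
        if all(h.end <= c.start or h.start >= c.end for c in chosen):
            chosen.append(h)
    chosen.sort(key=lambda h: h.start)
    return Architecture(("FBXD", *[h.model_id for h in chosen]))


def group_architectures(
    assignments: Mapping[str, Architecture],
) -> list[ArchitectureGroup]:
    """Partition proteins by canonical architecture string."""
    by_arch: dict[str, list[str]] = {}
    for name, arch in assignments.items():
        by_arch.setdefault(arch.canonical, []).append(name)
    return [
        ArchitectureGroup(arch, sorted(members))
        for arch, members in sorted(by_arch.items())
    ]


def enrichment_by_species(
    groups: Sequence[ArchitectureGroup],
    species_labels: Mapping[str, str],
    alpha: float = 0.05,
) -> list[dict]:
    """Per (species, architecture) verdict vs all other species pooled.

    Returns rows with one-sided p-values in both directions and the verdict
    at the given significance level.
    """
    species = sorted(set(species_labels.values()))
    if len(species) < 2:
        raise ValueError("need at least two species")
    totals = {sp: sum(1 for v in species_labels.values() if v == sp)
              for sp in species}
    grand_total = sum(totals.values())
    rows = []
    for grp in groups:
        counts = {sp: 0 for sp in species}
        for m in grp.members:
            counts[species_labels[m]] += 1
        n_arch = sum(counts.values())
        if n_arch == 0:
            continue
        for sp in species:
            a = counts[sp]
            b = totals[sp] - a
            c = n_arch - a
            d = (grand_total - totals[sp]) - c
            p_enriched = fisher_exact_one_sided(a, b, c, d)
            p_depleted = fisher_exact_one_sided(c, d, a, b)
            if p_enriched < alpha:
                verdict = "enriched"
            elif p_depleted < alpha:
                verdict = "depleted"
            else:
                verdict = "neither"
            rows.append({
                "species": sp,
                "architecture": grp.architecture,
                "count": a,
                "p_enriched": p_enriched,
                "p_depleted": p_depleted,
                "verdict": verdict,
            })
    return rows
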