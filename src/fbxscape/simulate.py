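"""Synthetic genomes with planted F-box-like gene families.

The generator emulates the data regime of a plant FBX superfamily survey at
desk scale: multi-member gene families sharing a conserved ~40-residue
N-terminal domain and variable C-terminal recruitment modules, arranged in
tandem arrays and collinear (segmental) blocks on several chromosomes;
pseudogene copies carry planted frameshifts and/or premature stop codons;
EST libraries are drawn from designated expressed loci with controlled
identity.  Everything is seeded and serialisable so downstream stages can
be scored against exact planted truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .intervals import GenomicInterval, Gff3Feature, write_fasta, write_gff3
from .seqs import (back_translate, random_dna, random_protein,
                   reverse_complement, translate, AMINO_ACIDS)

DOMAIN_LENGTH = 40
MODULE_NAMES = ("kelch", "lrr", "fba")
MODULE_LENGTH = 45


class SizingError(ValueError):
    """Requested loci do not fit on the configured chromosomes."""


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 3
    chromosome_length: int = 150_000
    n_coding_loci: int = 30
    n_pseudogene_loci: int = 20
    tandem_array_sizes: tuple[int, ...] = (3, 3, 2, 2)
    n_segmental_blocks: int = 1
    segmental_block_size: int = 6
    intron_count_range: tuple[int, int] = (0, 3)
    intron_length_range: tuple[int, int] = (80, 400)
    domain_model_id: str = "FBXD"
    domain_noise: float = 0.10   # per-position substitution, family domain
    member_noise: float = 0.05   # additional per-member substitution
    family_size: int = 6
    extra_refs_per_family: int = 2  # reference-only homologs (FBX_Ref depth)
    est_depth: float = 5.0
    est_identity: float = 0.97
    expression_prob_coding: float = 0.8
    expression_prob_pseudogene: float = 0.1
    gain_rate: float = 0.5
    loss_rate: float = 0.3

    def validate(self) -> None:
        counts = (self.n_chromosomes, self.chromosome_length,
                  self.n_coding_loci, self.n_pseudogene_loci,
                  self.n_segmental_blocks)
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if not 0 < self.est_identity <= 1:
            raise ValueError("est_identity must be in (0, 1]")
        if self.est_identity < 0.5:
            raise ValueError("est_identity < 0.5 is uninformative")
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.intron_count_range[0] > self.intron_count_range[1]:
            raise ValueError("bad intron_count_range")


@dataclass
class PlantedLocus:
    locus_id: str
    interval: GenomicInterval
    locus_class: str  # "coding" | "pseudogene"
    exons: list[GenomicInterval]
    strand: str
    cds: str  # spliced CDS in transcript orientation (post-mutation)
    protein: str  # founding protein (pre-mutation translation)
    architecture: str
    family: str
    duplication_mode: str  # "tandem" | "segmental" | "other"
    expressed: bool
    events: list[dict] = field(default_factory=list)
    fbxd_protein_range: tuple[int, int] = (0, DOMAIN_LENGTH)

    @property
    def fbxd_interval(self) -> GenomicInterval:
        """Genomic interval of the domain-encoding region (first exon side)."""
        span = 3 * DOMAIN_LENGTH
        iv = self.interval
        if self.strand == "+":
            return GenomicInterval(iv.sequence_id, iv.start,
                                   min(iv.start + span, iv.end), "+")
        return GenomicInterval(iv.sequence_id, max(iv.end - span, iv.start),
                               iv.end, "-")


@dataclass
class PlantedTruth:
    loci: list[PlantedLocus]
    domain_consensus: str
    module_consensus: dict[str, str]
    config: SimulationConfig
    event_log: list[dict] = field(default_factory=list)
    background_genes: list[tuple[str, int]] = field(default_factory=list)

    def by_id(self) -> dict[str, PlantedLocus]:
        return {l.locus_id: l for l in self.loci}

    def to_json(self) -> str:
        payload = {
            "domain_consensus": self.domain_consensus,
            "module_consensus": self.module_consensus,
            "config": asdict(self.config),
            "event_log": self.event_log,
            "background_genes": [[c, m] for c, m in self.background_genes],
            "loci": [
                {
                    **{k: v for k, v in asdict(l).items()
                       if k not in ("interval", "exons")},
                    "interval": [l.interval.sequence_id, l.interval.start,
                                 l.interval.end, l.interval.strand],
                    "exons": [[e.sequence_id, e.start, e.end, e.strand]
                              for e in l.exons],
                }
                for l in self.loci
            ],
        }
        return json.dumps(payload, indent=1, default=int)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        payload = json.loads(text)
        cfg_dict = payload["config"]
        for key in ("tandem_array_sizes", "intron_count_range",
                    "intron_length_range"):
            cfg_dict[key] = tuple(cfg_dict[key])
        loci = []
        for d in payload["loci"]:
            d = dict(d)
            d["interval"] = GenomicInterval(*d["interval"][:3],
                                            d["interval"][3])
            d["exons"] = [GenomicInterval(*e[:3], e[3]) for e in d["exons"]]
            d["fbxd_protein_range"] = tuple(d["fbxd_protein_range"])
            loci.append(PlantedLocus(**d))
        return cls(loci, payload["domain_consensus"],
                   payload["module_consensus"],
                   SimulationConfig(**cfg_dict), payload["event_log"],
                   [(c, m) for c, m in payload.get("background_genes", [])])


def _noisy(protein: str, rate: float, rng: np.random.Generator) -> str:
    out = list(protein)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = AMINO_ACIDS.replace(out[i], "")
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


_STOPS = ("TAA", "TAG", "TGA")


def _mutate_cds(cds: str, rate: float, rng: np.random.Generator) -> str:
    """Per-base substitution of a CDS; changes that would create an
    in-frame stop codon are suppressed, so coding copies stay coding."""
    out = list(cds)
    for i in range(len(out)):
        if rng.random() < rate:
            alt = "ACGT".replace(out[i], "")[rng.integers(3)]
            old = out[i]
            out[i] = alt
            ci = 3 * (i // 3)
            if "".join(out[ci : ci + 3]) in _STOPS:
                out[i] = old
    return "".join(out)


def plant_pseudogene(
    segment: str,
    exons: Sequence[tuple[int, int]],
    frameshift_positions: Sequence[int] = (),
    stop_positions: Sequence[int] = (),
) -> str:
    """Introduce pseudogene lesions into a genomic segment.

    Positions are CDS codon-level anchors: ``frameshift_positions`` are CDS
    base offsets where one base is deleted; ``stop_positions`` are CDS codon
    indices mutated to TAA.  All positions must fall inside coding exons.
    """
    # map CDS offsets to segment offsets
    cds_to_seg: list[int] = []
    for s, e in exons:
        cds_to_seg.extend(range(s, e))
    cds_len = len(cds_to_seg)

    edits: list[tuple[int, str]] = []  # (segment offset, op)
    for pos in frameshift_positions:
        if not 0 <= pos < cds_len:
            raise ValueError(f"frameshift position {pos} outside coding exons")
        edits.append((cds_to_seg[pos], "del"))
    for codon_idx in stop_positions:
        base = 3 * codon_idx
        if not 0 <= base + 2 < cds_len:
            raise ValueError(f"stop codon index {codon_idx} outside CDS")
        seg_positions = [cds_to_seg[base + k] for k in range(3)]
        if seg_positions != list(range(seg_positions[0], seg_positions[0] + 3)):
            raise ValueError("stop codon spans an intron boundary")
        edits.append((seg_positions[0], "taa"))

    out = list(segment)
    for off, op in sorted(edits, reverse=True):
        if op == "del":
            del out[off]
        else:
            out[off : off + 3] = "TAA"
    return "".join(out)


def _build_locus_segment(cds: str, cfg: SimulationConfig,
                         rng: np.random.Generator
                         ) -> tuple[str, list[tuple[int, int]], str]:
    """Insert GT..AG introns into a CDS.

    Returns (segment, exon list in segment coords, spliced CDS).
    """
    lo, hi = cfg.intron_count_range
    n_introns = int(rng.integers(lo, hi + 1))
    cut_sites = sorted(
        rng.choice(np.arange(12, len(cds) - 12), size=n_introns, replace=False)
    ) if n_introns else []
    segment = ""
    exons = []
    prev = 0
    for cut in cut_sites:
        ilen = int(rng.integers(*cfg.intron_length_range))
        intron = "GT" + random_dna(ilen - 4, rng) + "AG"
        exons.append((len(segment), len(segment) + (cut - prev)))
        segment += cds[prev:cut] + intron
        prev = cut
    exons.append((len(segment), len(segment) + len(cds) - prev))
    segment += cds[prev:]
    return segment, exons, cds


def generate_family_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], dict[str, str], PlantedTruth]:
    """Build genome FASTA dict, reference protein dict, and planted truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_total = config.n_coding_loci + config.n_pseudogene_loci

    domain_consensus = random_protein(DOMAIN_LENGTH, rng)
    module_consensus = {m: random_protein(MODULE_LENGTH, rng)
                        for m in MODULE_NAMES}

    # --- duplication-mode layout and family assignment --------------------
    # each placement group owns its families so planted mode labels are
    # unambiguous: a tandem array is one family; each collinear anchor pair
    # of a segmental block is one two-member family; singleton loci form
    # families whose members land on different chromosomes
    classes = ["coding"] * config.n_coding_loci + \
              ["pseudogene"] * config.n_pseudogene_loci
    order = list(range(n_total))
    rng.shuffle(order)

    locus_family: dict[int, int] = {}
    fam_counter = 0

    def new_family() -> int:
        nonlocal fam_counter
        fam_counter += 1
        return fam_counter - 1

    placements: list[list[int]] = []  # tandem arrays, placed contiguously
    modes = {}
    idx = 0
    for size in config.tandem_array_sizes:
        if idx + size > n_total:
            break
        group = order[idx : idx + size]
        fam = new_family()
        for g in group:
            locus_family[g] = fam
            modes[g] = "tandem"
        placements.append(group)
        idx += size
    seg_pairs: list[tuple[list[int], list[int]]] = []
    for _ in range(config.n_segmental_blocks):
        size = config.segmental_block_size
        if idx + 2 * size > n_total:
            break
        run_a = order[idx : idx + size]
        run_b = order[idx + size : idx + 2 * size]
        for a, b in zip(run_a, run_b):
            fam = new_family()
            locus_family[a] = locus_family[b] = fam
            modes[a] = modes[b] = "segmental"
        seg_pairs.append((run_a, run_b))
        idx += 2 * size
    singles = order[idx:]
    chunk = max(2, min(config.family_size, config.n_chromosomes))
    for k, g in enumerate(singles):
        if k % chunk == 0:
            fam = new_family()
        locus_family[g] = fam
        modes[g] = "other"

    # --- family profiles ---------------------------------------------------
    n_families = fam_counter
    fam_profiles = []
    for f in range(n_families):
        dom = _noisy(domain_consensus, config.domain_noise, rng)
        mod_choice = rng.integers(len(MODULE_NAMES) + 1)
        if mod_choice < len(MODULE_NAMES):
            mname = MODULE_NAMES[mod_choice]
            mod = _noisy(module_consensus[mname], config.domain_noise, rng)
            arch = f"FBXD+{mname}"
        else:
            mname, mod, arch = None, "", "FBXD"
        tail = random_protein(int(rng.integers(40, 70)), rng)
        linker = random_protein(5, rng)
        protein = dom + linker + mod + tail
        fam_profiles.append({
            "family": f"fam{f:02d}",
            "protein": protein,
            # one founding CDS per family: members diverge from it at the
            # nucleotide level so synonymous divergence stays realistic
            "cds": back_translate(protein, rng),
            "architecture": arch,
        })

    # --- build locus segments --------------------------------------------
    loci_build: dict[int, dict] = {}
    for g in range(n_total):
        fam = fam_profiles[locus_family[g]]
        member_cds = _mutate_cds(fam["cds"], config.member_noise, rng)
        protein = translate(member_cds)
        segment, exons, cds = _build_locus_segment(member_cds, config, rng)
        events = []
        if classes[g] == "pseudogene":
            n_events = int(rng.integers(1, 3))
            cds_len = len(cds)
            fs_positions, stop_codons = [], []
            for _ in range(n_events):
                if rng.random() < 0.5:
                    pos = int(rng.integers(30, cds_len - 30))
                    fs_positions.append(pos)
                    events.append({"type": "frameshift", "cds_pos": pos})
                else:
                    codon = int(rng.integers(10, cds_len // 3 - 10))
                    base = _cds_to_seg(exons, 3 * codon)
                    if _cds_to_seg(exons, 3 * codon + 2) != base + 2:
                        continue  # codon straddles an intron: skip event
                    stop_codons.append(codon)
                    events.append({"type": "stop", "codon": codon})
            if not events:  # guarantee at least one lesion
                pos = int(rng.integers(30, cds_len - 30))
                fs_positions.append(pos)
                events.append({"type": "frameshift", "cds_pos": pos})
            segment = plant_pseudogene(segment, exons,
                                       frameshift_positions=fs_positions,
                                       stop_positions=stop_codons)
            # exon coordinates shift left past each deleted base
            del_sites = sorted(_cds_to_seg(exons, p) for p in fs_positions)
            exons = [
                (s - sum(1 for d in del_sites if d < s),
                 e - sum(1 for d in del_sites if d < e))
                for s, e in exons
            ]
        loci_build[g] = {
            "segment": segment,
            "exons": exons,
            "cds": cds,
            "protein": protein,
            "events": events,
            "family": fam_profiles[locus_family[g]]["family"],
            "architecture": fam_profiles[locus_family[g]]["architecture"],
        }

    # --- place on chromosomes --------------------------------------------
    # tandem arrays and segmental runs rotate over chromosomes; each
    # singleton family spreads its members across distinct chromosomes, and
    # group order along every chromosome is shuffled so singleton families
    # do not line up into spurious collinear patterns
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_parts: dict[str, list[str]] = {c: [] for c in chrom_names}
    chrom_len: dict[str, int] = {c: 0 for c in chrom_names}
    planted: list[PlantedLocus] = []
    background: list[tuple[str, int]] = []  # filler (non-family) genes

    queues: dict[str, list[tuple[str, list[int]]]] = {c: [] for c in chrom_names}
    ci = 0
    for grp in placements:
        queues[chrom_names[ci % len(chrom_names)]].append(("tandem", grp))
        ci += 1
    for run_a, run_b in seg_pairs:
        queues[chrom_names[ci % len(chrom_names)]].append(("seg", run_a))
        ci += 1
        queues[chrom_names[ci % len(chrom_names)]].append(("seg", run_b))
        ci += 1
    for k in range(0, len(singles), chunk):
        members = singles[k : k + chunk]
        perm = rng.permutation(len(chrom_names))
        for m, p in zip(members, perm):
            queues[chrom_names[int(p)]].append(("single", [m]))
    for c in chrom_names:
        rng.shuffle(queues[c])

    def add_gap(chrom: str, gap: int) -> None:
        # intergenic spacer with filler gene positions at plant-like
        # density, so gene-order coordinates behave like a real annotation
        chrom_parts[chrom].append(random_dna(gap, rng))
        start = chrom_len[chrom]
        for off in range(600, gap - 400, 1200):
            background.append((chrom, start + off))
        chrom_len[chrom] += gap

    def place_group(chrom: str, members: list[int], group_kind: str) -> None:
        strand = "+" if rng.random() < 0.5 else "-"
        for k, g in enumerate(members):
            gap = int(rng.integers(600, 2500)) if k and group_kind != "single" \
                else int(rng.integers(3000, 9000))
            add_gap(chrom, gap)
            b = loci_build[g]
            seg = b["segment"]
            off = chrom_len[chrom]
            if strand == "-":
                placed = reverse_complement(seg)
                exon_ivs = [
                    GenomicInterval(chrom, off + len(seg) - e,
                                    off + len(seg) - s, "-")
                    for s, e in reversed(b["exons"])
                ]
            else:
                placed = seg
                exon_ivs = [GenomicInterval(chrom, off + s, off + e, "+")
                            for s, e in b["exons"]]
            chrom_parts[chrom].append(placed)
            chrom_len[chrom] += len(seg)
            planted.append(PlantedLocus(
                locus_id=f"locus{g:03d}",
                interval=GenomicInterval(chrom, off, off + len(seg), strand),
                locus_class=classes[g],
                exons=exon_ivs,
                strand=strand,
                cds=_splice(b["segment"], b["exons"]),
                protein=b["protein"],
                architecture=b["architecture"],
                family=b["family"],
                duplication_mode=modes[g],
                expressed=bool(
                    rng.random() < (config.expression_prob_coding
                                    if classes[g] == "coding"
                                    else config.expression_prob_pseudogene)),
                events=b["events"],
            ))

    for chrom in chrom_names:
        for kind, members in queues[chrom]:
            place_group(chrom, members, kind)

    for chrom in chrom_names:
        pad = config.chromosome_length - chrom_len[chrom]
        if pad < 0:
            raise SizingError(
                f"{chrom} needs {chrom_len[chrom]} bases but only "
                f"{config.chromosome_length} configured")
        add_gap(chrom, pad)
    genome = {c: "".join(chrom_parts[c]) for c in chrom_names}

    references = {
        l.locus_id: l.protein for l in planted if l.locus_class == "coding"
    }
    # reference-only homologs: the real reference collection is far deeper
    # than any one genome, so every locus has close non-self references
    for fam in fam_profiles:
        for k in range(config.extra_refs_per_family):
            ref_cds = _mutate_cds(fam["cds"], config.member_noise, rng)
            references[f"ref_{fam['family']}_{k}"] = translate(ref_cds)
    planted.sort(key=lambda l: l.locus_id)
    truth = PlantedTruth(planted, domain_consensus, module_consensus, config,
                         background_genes=sorted(background))
    return genome, references, truth


def _cds_to_seg(exons: Sequence[tuple[int, int]], cds_pos: int) -> int:
    mapping = []
    for s, e in exons:
        mapping.extend(range(s, e))
    return mapping[cds_pos]


def _splice(segment: str, exons: Sequence[tuple[int, int]]) -> str:
    return "".join(segment[s:e] for s, e in exons)


def generate_est_library(
    truth: PlantedTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Draw ESTs from designated expressed loci.

    Read count per expressed locus ~ Poisson(est_depth); each read is a
    random CDS substring (>= 50 nt) with exactly
    floor((1 - est_identity) * length) substitutions, so read identity is
    always >= est_identity.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    ests: dict[str, str] = {}
    for locus in truth.loci:
        if not locus.expressed:
            continue
        n_reads = int(rng.poisson(config.est_depth))
        cds = locus.cds
        for r in range(n_reads):
            length = int(rng.integers(100, min(301, len(cds) + 1)))
            length = max(length, 50)
            start = int(rng.integers(0, len(cds) - length + 1))
            read = list(cds[start : start + length])
            n_mut = int((1 - config.est_identity) * length)
            if n_mut:
                sites = rng.choice(length, size=n_mut, replace=False)
                for s in sites:
                    alt = "ACGT".replace(read[s], "")
                    read[s] = alt[rng.integers(3)]
            ests[f"est_{locus.locus_id}_{r}"] = "".join(read)
    return ests


def _branch_label(node: dendropy.Node) -> str:
    """Stable branch id: the sorted descendant leaf labels of the child node."""
    leaves = sorted(l.taxon.label for l in node.leaf_iter())
    return leaves[0] if len(leaves) == 1 else "+".join(leaves)


def simulate_birth_death_scenario(
    species_tree: dendropy.Tree | str,
    gain_rate: float,
    loss_rate: float,
    seed: int,
    root_size: int = 10,
) -> tuple[dict[str, list[str]], list[dict]]:
    """Gene gain/loss along a species tree with per-branch Poisson events.

    Gene labels carry their full duplication lineage, so true orthology is
    recoverable.  Returns (leaf gene sets keyed by species, event log).
    """
    if gain_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    if isinstance(species_tree, str):
        species_tree = dendropy.Tree.get(data=species_tree, schema="newick")
    rng = np.random.default_rng(seed)
    root_genes = [f"g{i}" for i in range(root_size)]
    event_log: list[dict] = []
    node_genes: dict[int, list[str]] = {}

    for node in species_tree.preorder_node_iter():
        if node.parent_node is None:
            node_genes[id(node)] = list(root_genes)
            continue
        genes = list(node_genes[id(node.parent_node)])
        branch = _branch_label(node)
        n_gain = int(rng.poisson(gain_rate))
        n_loss = int(rng.poisson(loss_rate))
        for k in range(n_gain):
            if genes:
                src = genes[int(rng.integers(len(genes)))]
            else:
                src = f"g{root_size + len(event_log)}"
            child = f"{src}.{branch}{k}"
            genes.append(child)
            event_log.append({"branch": branch, "type": "gain",
                              "gene": child, "source": src})
        for _ in range(n_loss):
            if not genes:
                break
            victim = genes.pop(int(rng.integers(len(genes))))
            event_log.append({"branch": branch, "type": "loss",
                              "gene": victim})
        node_genes[id(node)] = genes

    leaf_sets = {
        leaf.taxon.label: sorted(node_genes[id(leaf)])
        for leaf in species_tree.leaf_node_iter()
    }
    return leaf_sets, event_log


def replay_event_log(
    species_tree: dendropy.Tree | str,
    root_size: int,
    event_log: list[dict],
) -> dict[str, int]:
    """Replay net gains/losses down the tree to per-species family sizes."""
    if isinstance(species_tree, str):
        species_tree = dendropy.Tree.get(data=species_tree, schema="newick")
    by_branch: dict[str, int] = {}
    for ev in event_log:
        by_branch.setdefault(ev["branch"], 0)
        by_branch[ev["branch"]] += 1 if ev["type"] == "gain" else -1
    sizes: dict[int, int] = {}
    out: dict[str, int] = {}
    for node in species_tree.preorder_node_iter():
        if node.parent_node is None:
            sizes[id(node)] = root_size
        else:
            sizes[id(node)] = sizes[id(node.parent_node)] + \
                by_branch.get(_branch_label(node), 0)
        if node.is_leaf():
            out[node.taxon.label] = sizes[id(node)]
    return out


def write_simulation(
    out_dir: str | Path,
    genome: Mapping[str, str],
    references: Mapping[str, str],
    truth: PlantedTruth,
    ests: Mapping[str, str] | None = None,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(genome, out / "genome.fa")
    write_fasta(references, out / "references.fa")
    if ests is not None:
        write_fasta(ests, out / "ests.fa")
    (out / "truth.json").write_text(truth.to_json())
    features = []
    for locus in truth.loci:
        ftype = "gene" if locus.locus_class == "coding" else "pseudogene"
        attrs = {"ID": locus.locus_id, "family": locus.family,
                 "class": locus.locus_class}
        features.append(Gff3Feature(locus.interval, ftype, attrs))
        for k, exon in enumerate(locus.exons):
            features.append(Gff3Feature(
                exon, "CDS", {"ID": f"{locus.locus_id}.cds{k}",
                              "Parent": locus.locus_id}))
    write_gff3(features, out / "loci.gff3")
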