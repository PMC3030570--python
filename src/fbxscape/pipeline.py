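"""End-to-end orchestration: simulate -> search -> annotate -> classify ->
cluster -> reconcile -> select -> duplication-mode -> expression, with a
consolidated, deterministic report.

The default run generates a synthetic genome with planted truth, so every
stage's output can be scored (locus recovery, classification F1,
duplication-mode precision/recall, expression contrasts).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
import numpy as np

from . import annotation, dupmode, orthology, selection, stats, trees
from .intervals import GenomicInterval
from .search import dedup_collection, translated_search
from .seqs import translate
from .simulate import (PlantedTruth, SimulationConfig, generate_est_library,
                       generate_family_genome, simulate_birth_death_scenario)
from .spliced import SplicedScoring


@dataclass
class PipelineConfig:
    """All pipeline thresholds, with the published survey's defaults."""

    seed: int = 0
    tblastn_e: float = 1.0          # initial domain search cutoff
    blastx_e: float = 1e-5          # CTT reference search cutoff
    window_size: int = 10_000       # annotation window
    ctt_max_iter: int = 6
    min_spliced_score: float = 50.0
    query_dedup_identity: float = 0.90
    mcl_inflation: float = 4.0
    graph_e_cutoff: float = 1e-5
    sts_max_bin: int = 4
    ks_min: float = 0.005
    ks_max: float = 3.0
    lrt_critical: float = 3.84
    min_block_pairs: int = 6
    tandem_max_intervening: int = 10
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> None:
        if self.ks_min > self.ks_max:
            raise ValueError("ks_min must not exceed ks_max")
        if self.tblastn_e <= 0 or self.blastx_e <= 0:
            raise ValueError("E-value cutoffs must be positive")
        if self.ctt_max_iter < 1:
            raise ValueError("ctt_max_iter must be >= 1")
        self.simulation.validate()

    def scoring(self) -> SplicedScoring:
        return SplicedScoring(min_score=self.min_spliced_score)


def merge_hit_regions(hits, merge_gap: int = 150) -> list[GenomicInterval]:
    """Collapse overlapping or near-adjacent translated-search hits into
    candidate regions, keeping each region's best hit interval.

    ``merge_gap`` joins split hits of one domain (e.g. partial hits from
    different reading frames around a planted lesion)."""
    by_chrom: dict[str, list] = {}
    for h in hits:
        if h.interval is not None:
            by_chrom.setdefault(h.interval.sequence_id, []).append(h)
    regions = []
    for chrom in sorted(by_chrom):
        chrom_hits = sorted(by_chrom[chrom],
                            key=lambda h: (h.interval.start, -h.raw_score))
        clusters: list[list] = []
        for h in chrom_hits:
            if clusters and h.interval.start < merge_gap + max(
                    x.interval.end for x in clusters[-1]):
                clusters[-1].append(h)
            else:
                clusters.append([h])
        for cluster in clusters:
            best = max(cluster, key=lambda h: h.raw_score)
            regions.append(best.interval)
    return regions


def dedupe_models(models) -> list:
    """Drop models covering the same locus (>=50% mutual overlap), keeping
    the highest-scoring one."""
    kept = []
    for m in sorted(models, key=lambda m: (-m.best_score, m.locus_id)):
        iv = m.interval
        dup = any(
            iv.intersection_length(k.interval)
            >= 0.5 * min(len(iv), len(k.interval))
            for k in kept
        )
        if not dup:
            kept.append(m)
    kept.sort(key=lambda m: (m.interval.sequence_id, m.interval.start))
    return kept


@dataclass
class RunReport:
    config: dict
    candidate_regions: int = 0
    annotated: int = 0
    coding: int = 0
    pseudogene: int = 0
    unresolved: int = 0
    omitted: int = 0
    locus_recovery: float = float("nan")
    classification_f1: float = float("nan")
    og_count: int = 0
    bins: dict = field(default_factory=dict)
    gain_loss: dict = field(default_factory=dict)
    kaks_classes: dict = field(default_factory=dict)
    dup_modes: dict = field(default_factory=dict)
    dup_precision_recall: dict = field(default_factory=dict)
    expression_p: dict = field(default_factory=dict)
    stage_log: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True, default=float)


def run_pipeline(config: PipelineConfig) -> tuple[RunReport, dict]:
    """Execute all stages on a simulated genome; returns (report, artifacts).

    ``artifacts`` carries the intermediate objects (genome, truth, models,
    clusters, records) for callers that inspect more than the summary.
    """
    config.validate()
    report = RunReport(config=asdict(config))
    art: dict = {}

    # -- stage 1: simulate -------------------------------------------------
    genome, references, truth = generate_family_genome(config.simulation)
    ests = generate_est_library(truth, config.simulation)
    art.update(genome=genome, references=references, truth=truth, ests=ests)
    report.stage_log.append(f"simulate: {len(truth.loci)} planted loci")

    # -- stage 2: domain search -------------------------------------------
    queries = {name: prot[:40] for name, prot in references.items()}
    queries = dedup_collection(queries, config.query_dedup_identity)
    hits = translated_search(queries, genome, config.tblastn_e)
    regions = merge_hit_regions(hits)
    report.candidate_regions = len(regions)
    art["regions"] = regions
    report.stage_log.append(
        f"search: {len(queries)} queries, {len(hits)} hits, "
        f"{len(regions)} candidate regions")

    # -- stage 3: annotation (CTT + consensus) -----------------------------
    scoring = config.scoring()
    models = []
    for region in regions:
        model = annotation.annotate_locus(
            region, genome, references, scoring,
            window_size=config.window_size, max_iter=config.ctt_max_iter,
            e_cutoff=config.blastx_e)
        if model is None:
            report.omitted += 1
        elif model.interval is not None:
            models.append(model)
    models = dedupe_models(models)
    art["models"] = models
    report.annotated = len(models)
    for m in models:
        setattr(report, m.classification,
                getattr(report, m.classification) + 1)
    report.stage_log.append(
        f"annotate: {len(models)} models ({report.omitted} omitted)")

    # -- stage 4: truth comparison ----------------------------------------
    matches = _match_truth(models, truth)
    art["matches"] = matches
    recovered = {t for t, _ in matches.items() if _ is not None}
    report.locus_recovery = len(recovered) / len(truth.loci)
    tp = fp = fn = 0
    for locus in truth.loci:
        model = matches.get(locus.locus_id)
        if model is None or model.classification == "unresolved":
            continue
        truth_pseudo = locus.locus_class == "pseudogene"
        called_pseudo = model.classification == "pseudogene"
        if truth_pseudo and called_pseudo:
            tp += 1
        elif called_pseudo:
            fp += 1
        elif truth_pseudo:
            fn += 1
    denom = 2 * tp + fp + fn
    report.classification_f1 = 2 * tp / denom if denom else float("nan")

    # -- stage 5: orthology on predicted proteins --------------------------
    proteins = {
        m.locus_id: translate(m.cds).rstrip("*").replace("*", "X")
        for m in models
    }
    species_map = {name: "S1" for name in proteins}
    graph = orthology.build_similarity_graph(
        proteins, species_map, config.graph_e_cutoff)
    clusters = orthology.mcl_cluster(graph, config.mcl_inflation)
    ogs = orthology.assign_bins(clusters, species_map, config.sts_max_bin)
    art.update(graph=graph, clusters=clusters, ogs=ogs)
    report.og_count = len(ogs)
    for og in ogs:
        key = str(og.bin)
        report.bins[key] = report.bins.get(key, 0) + 1

    # -- stage 6: birth/death on the packaged species tree -----------------
    sp_tree = trees.load_species_tree()
    leaf_sets, event_log = simulate_birth_death_scenario(
        sp_tree, config.simulation.gain_rate,
        config.simulation.loss_rate, config.seed)
    summaries, singles = _scenario_reconciliations(sp_tree, leaf_sets)
    totals = trees.aggregate_gains_losses(summaries, singles)
    report.gain_loss = {
        "total_gains": totals.total_gains,
        "total_losses": totals.total_losses,
    }
    art.update(event_log=event_log, gain_loss=totals)

    # -- stage 7: selection -------------------------------------------------
    cds_db = {m.locus_id: _trim_cds(m.cds) for m in models
              if m.classification == "coding" and len(m.cds) >= 90}
    prot_db = {k: translate(v) for k, v in cds_db.items()}
    prot_db = {k: v for k, v in prot_db.items() if "*" not in v}
    cds_db = {k: cds_db[k] for k in prot_db}
    records = {}
    for name in sorted(cds_db):
        try:
            recs = selection.kaks_for_locus(name, cds_db, prot_db,
                                            seed=config.seed)
        except ValueError:
            continue
        records[name] = recs["full"]
    art["kaks"] = records
    for rec in records.values():
        report.kaks_classes[rec.selection_class] = \
            report.kaks_classes.get(rec.selection_class, 0) + 1

    # -- stage 8: duplication mode -----------------------------------------
    positions = _gene_positions(models, truth.background_genes)
    pairs = sorted({
        (min(a, b), max(a, b))
        for cluster in clusters
        for a in cluster for b in cluster
        if a < b and a in positions and b in positions
    })
    modes = dupmode.classify_all(
        sorted(positions), pairs, positions,
        config.min_block_pairs, max_intervening=config.tandem_max_intervening)
    art["dup_modes"] = modes
    for mode in modes.values():
        report.dup_modes[mode] = report.dup_modes.get(mode, 0) + 1
    report.dup_precision_recall = _dup_scores(modes, matches, truth)

    # -- stage 9: expression ------------------------------------------------
    model_cds = {m.locus_id: m.cds for m in models}
    evidence = stats.map_ests(ests, model_cds)
    labels = {}
    og_scale = {}
    for og in ogs:
        for member in og.members:
            og_scale[member] = og.scale
    for m in models:
        if m.classification == "pseudogene":
            labels[m.locus_id] = "pseudogene"
        elif m.classification == "coding":
            labels[m.locus_id] = ("LTSP" if og_scale.get(m.locus_id) == "LTS"
                                  else "STSP")
    expressed = {k: v.expressed for k, v in evidence.items()}
    report.expression_p = stats.group_expression_tests(expressed, labels)
    art.update(evidence=evidence, labels=labels)
    report.stage_log.append("expression: %d loci with EST support"
                            % sum(expressed.values()))
    return report, art


def _trim_cds(cds: str) -> str:
    return cds[: len(cds) - len(cds) % 3]


def _match_truth(models, truth: PlantedTruth):
    """Greedy best-overlap matching of models to planted loci."""
    out = {}
    for locus in truth.loci:
        best, best_ov = None, 0
        for m in models:
            iv = m.interval
            if iv is None:
                continue
            ov = locus.interval.intersection_length(iv)
            if ov > best_ov:
                best, best_ov = m, ov
        if best is not None and best_ov >= 0.5 * len(locus.interval):
            out[locus.locus_id] = best
        else:
            out[locus.locus_id] = None
    return out


def _gene_positions(models, background=()) -> dict[str, dupmode.GenePosition]:
    """Gene-order coordinates over family models plus background genes
    (ordinals must reflect the whole annotation, not just the family)."""
    by_chrom: dict[str, list] = {}
    for m in models:
        iv = m.interval
        if iv is not None:
            by_chrom.setdefault(iv.sequence_id, []).append(
                (iv.midpoint, m.locus_id))
    for chrom, midpoint in background:
        by_chrom.setdefault(chrom, []).append((midpoint, None))
    positions = {}
    for chrom in sorted(by_chrom):
        for k, (mid, locus_id) in enumerate(sorted(by_chrom[chrom])):
            if locus_id is not None:
                positions[locus_id] = dupmode.GenePosition(
                    locus_id, chrom, k, mid)
    return positions


def reannotation_identities(truth: PlantedTruth, matches) -> list[float]:
    """Alignment identity of each recovered coding model's CDS to the
    planted CDS (the survey-style re-annotation self-check)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    idents = []
    for locus in truth.loci:
        model = matches.get(locus.locus_id)
        if locus.locus_class != "coding" or model is None \
                or model.classification != "coding":
            continue
        a, b = locus.cds, model.cds
        if a == b:
            idents.append(1.0)
            continue
        aln = aligner.align(a, b)[0]
        same = sum(1 for (qs, qe), (ts, te) in zip(*aln.aligned)
                   for x, y in zip(a[qs:qe], b[ts:te]) if x == y)
        idents.append(same / max(len(a), len(b)))
    return idents


def _dup_scores(modes, matches, truth: PlantedTruth) -> dict:
    out = {}
    for target in ("tandem", "segmental"):
        tp = fp = fn = 0
        for locus in truth.loci:
            model = matches.get(locus.locus_id)
            called = modes.get(model.locus_id) if model is not None else None
            if called == target and locus.duplication_mode == target:
                tp += 1
            elif called == target:
                fp += 1
            elif locus.duplication_mode == target:
                fn += 1
        precision = tp / (tp + fp) if tp + fp else float("nan")
        recall = tp / (tp + fn) if tp + fn else float("nan")
        out[target] = {"precision": precision, "recall": recall}
    return out


def _scenario_reconciliations(sp_tree, leaf_sets):
    """Build per-family gene trees from a birth/death scenario and
    reconcile each against the species tree."""
    families: dict[str, dict[str, list[str]]] = {}
    for species, genes in leaf_sets.items():
        for g in genes:
            root = g.split(".")[0]
            families.setdefault(root, {}).setdefault(species, []).append(g)
    summaries = []
    singles = []
    for root in sorted(families):
        members = families[root]
        n_species = len(members)
        size = sum(len(v) for v in members.values())
        if n_species == 1:
            singles.append((next(iter(members)), size))
            continue
        labels = sorted(f"{sp}|{g}" for sp, genes in members.items()
                        for g in genes)
        species_map = {lab: lab.split("|")[0] for lab in labels}
        if len(labels) < 3:
            # two-leaf family: reconcile the trivial cherry
            import dendropy
            taxa = dendropy.TaxonNamespace(labels)
            gt = dendropy.Tree(taxon_namespace=taxa)
            for lab in labels:
                node = dendropy.Node(taxon=taxa.get_taxon(lab))
                gt.seed_node.add_child(node)
            summary = trees.reconcile(gt, sp_tree, species_map)
        else:
            D = _label_distance_matrix(labels, _SpeciesGeometry(sp_tree))
            gt = trees.nj_tree(D, labels)
            gt, summary = trees.root_by_dl(gt, sp_tree, species_map)
        summaries.append((n_species, summary))
    return summaries, singles


class _SpeciesGeometry:
    """Depth/LCA helper over the species tree (unit branch lengths)."""

    def __init__(self, sp_tree):
        self.ancestors: dict[str, list[int]] = {}
        self.depth: dict[int, int] = {}
        for node in sp_tree.preorder_node_iter():
            p = node.parent_node
            self.depth[id(node)] = 0 if p is None else self.depth[id(p)] + 1
        for leaf in sp_tree.leaf_node_iter():
            path = []
            node = leaf
            while node is not None:
                path.append(id(node))
                node = node.parent_node
            self.ancestors[leaf.taxon.label] = path

    def lca_depth(self, species: set[str]) -> int:
        common = None
        for sp in species:
            ids = set(self.ancestors[sp])
            common = ids if common is None else common & ids
        return max(self.depth[i] for i in common)

    def leaf_depth(self, sp: str) -> int:
        return self.depth[self.ancestors[sp][0]]


def _gain_branch_species(part: str) -> set[str]:
    """'Al+At0' -> {'Al', 'At'}: leaf set of the branch a gain happened on."""
    return set(part.rstrip("0123456789").split("+"))


def _label_distance_matrix(labels, geo: _SpeciesGeometry):
    """Additive gene distances for a birth/death scenario family.

    Two copies diverged at the species-tree point of either their species
    split (same duplication lineage) or the gain event where their lineages
    separated; distance = depth distance of both species to that point,
    plus a small per-duplication offset so paralog splits precede
    speciations on the same branch.
    """
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sp_a, gene_a = labels[i].split("|")
            sp_b, gene_b = labels[j].split("|")
            a = gene_a.split(".")
            b = gene_b.split(".")
            shared = 0
            for x, y in zip(a, b):
                if x == y:
                    shared += 1
                else:
                    break
            involved = {sp_a, sp_b}
            for part in a[shared:] + b[shared:]:
                if part and part != a[0]:
                    involved |= _gain_branch_species(part)
            lineage = len(a) + len(b) - 2 * shared
            p_depth = geo.lca_depth(involved)
            d = ((geo.leaf_depth(sp_a) - p_depth)
                 + (geo.leaf_depth(sp_b) - p_depth)
                 + 0.2 * lineage + 0.01)
            D[i, j] = D[j, i] = d
    return D


def write_report(report: RunReport, out_dir: str | Path) -> list[Path]:
    """Persist the report as JSON plus flat TSV tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    js = out / "report.json"
    js.write_text(report.to_json())
    written.append(js)
    counts = out / "counts.tsv"
    with open(counts, "w") as fh:
        fh.write("metric\tvalue\n")
        for key in ("candidate_regions", "annotated", "coding", "pseudogene",
                    "unresolved", "omitted", "locus_recovery",
                    "classification_f1", "og_count"):
            fh.write(f"{key}\t{getattr(report, key)}\n")
    written.append(counts)
    tables = {
        "kaks_classes.tsv": report.kaks_classes,
        "dup_modes.tsv": report.dup_modes,
        "expression_p.tsv": report.expression_p,
        "bins.tsv": report.bins,
    }
    for name, mapping in tables.items():
        path = out / name
        with open(path, "w") as fh:
            fh.write("key\tvalue\n")
            for k in sorted(mapping):
                fh.write(f"{k}\t{mapping[k]}\n")
        written.append(path)
    return written
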