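"""Seeded generator for a complete synthetic candidate-discovery study.

The generator emits every input the pipeline consumes — an expression atlas
with tissue/replicate structure, a paired metabolite matrix, a toy genome
layout, domain/BLAST/GO tables, label lists and a latex-proteome list —
with planted ground truth so each downstream stage has a recoverable
signal:

* a co-expressed MIA module (labelled positives plus unlabelled ADH
  discovery targets) sharing one latent tissue profile, with linked
  metabolites riding the same profile;
* flat-profile, well-expressed "housekeeping" negatives emulating
  conserved single-copy genes, which are not expected to belong to a
  specialized pathway;
* anchor + whitelist-Pfam-neighbour gene clusters planted within the
  scanner's 100 kb window, plus near-miss decoys placed just beyond it.

Everything is driven by one seed; identical config + seed reproduces
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    BlastHit,
    DomainAnnotation,
    GeneModel,
    write_blast_tab,
    write_domain_table,
    write_gene_models,
    write_matrix,
)

#: Pfam accessions scanned for around cluster anchors (version-agnostic).
WHITELIST_PFAM = frozenset(
    {"PF03171", "PF14226", "PF00891", "PF08240", "PF00067", "PF08031", "PF00201"}
)

#: ADH family marker domains.
MDR_PFAM = ("PF00107", "PF08240")
SDR_PFAM = "PF00106"
AKR_PFAM = "PF00248"

#: Oxidoreductase GO terms used by the latex-proteome filter.
GO_OXIDATION_REDUCTION = "GO:0055114"
GO_OXIDOREDUCTASE = "GO:0016491"

_DECOY_PFAM = "PF00067"  # cytochrome P450, whitelisted but non-ADH
_FILLER_PFAMS = ("PF00069", "PF00646", "PF07714", "PF00010", "PF02365")
_FILLER_GO = ("GO:0008150", "GO:0003674", "GO:0005575", "GO:0006355")


class ConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic data.

    Defaults emulate the published study design: a 16-tissue atlas with 6
    replicates per tissue (96 samples; the deposited atlas has 94, reachable
    with ``drop_samples=2``), 75 labelled MIA-module genes and 1908
    flat-profile conserved negatives, a small panel of quantified alkaloids
    of which 9 track the module profile, and a toy genome carrying planted
    anchor + whitelist-neighbour clusters inside the 100 kb scan window with
    near-miss decoys just outside it.
    """

    seed: int = 0
    # atlas design
    n_tissues: int = 16
    replicates_per_tissue: int = 6
    drop_samples: int = 0
    n_genes: int = 3000
    n_mia_module: int = 75
    n_module_adh: int = 24
    n_negatives: int = 1908
    n_metabolites: int = 14
    n_metabolites_linked: int = 9
    # expression model (log2-TPM scale)
    module_signal_sd: float = 2.0
    module_noise_sd: float = 0.4
    tissue_effect_sd: float = 1.0
    replicate_noise_sd: float = 0.8
    negative_noise_sd: float = 0.3
    baseline_logmean: float = 3.0
    baseline_logsd: float = 2.0
    module_baseline_logmean: float = 5.0
    module_baseline_logsd: float = 1.0
    # genome layout
    n_contigs: int = 20
    genes_per_contig: int = 150
    mean_gene_len: int = 3000
    mean_intergenic: int = 15000
    n_planted_clusters: int = 4
    cluster_members_per_anchor: int = 3
    cluster_span_bp: int = 80000
    n_decoy_near_misses: int = 4
    scan_window: int = 100000
    n_scattered_adh: int = 40
    # GO table and latex proteome
    proteome_size: int = 120
    proteome_adh_inclusion: float = 0.8
    go_oxidoreductase_fraction: float = 0.9

    def validate(self) -> None:
        counts = {
            k: getattr(self, k)
            for k in (
                "n_tissues",
                "replicates_per_tissue",
                "n_genes",
                "n_mia_module",
                "n_module_adh",
                "n_negatives",
                "n_metabolites",
                "n_metabolites_linked",
                "n_contigs",
                "n_planted_clusters",
                "n_decoy_near_misses",
                "n_scattered_adh",
                "drop_samples",
            )
        }
        for name, v in counts.items():
            if v < 0:
                raise ConfigError(f"{name} must be >= 0, got {v}")
        if self.n_mia_module + self.n_module_adh + self.n_negatives > self.n_genes:
            raise ConfigError(
                "n_mia_module + n_module_adh + n_negatives exceeds n_genes"
            )
        if self.n_metabolites_linked > self.n_metabolites:
            raise ConfigError("n_metabolites_linked exceeds n_metabolites")
        if self.cluster_span_bp >= 2 * self.scan_window:
            raise ConfigError(
                "cluster_span_bp must stay below twice the scan window, or a "
                "planted cluster cannot be guaranteed recoverable"
            )
        planted_stretch = (self.cluster_members_per_anchor + 1) * (
            self.mean_gene_len + self.mean_intergenic
        )
        if self.n_planted_clusters and planted_stretch > self.cluster_span_bp:
            raise ConfigError(
                f"cluster_members_per_anchor x (gene+intergenic) = "
                f"{planted_stretch} bp does not fit cluster_span_bp "
                f"{self.cluster_span_bp}"
            )
        if self.n_planted_clusters > self.n_contigs:
            raise ConfigError("more planted clusters than contigs")
        if self.drop_samples >= self.n_tissues * self.replicates_per_tissue:
            raise ConfigError("drop_samples removes the whole atlas")


@dataclass
class GroundTruth:
    """What was planted, for oracle checks against recovered results."""

    module_gene_ids: set[str] = field(default_factory=set)
    module_adh_gene_ids: set[str] = field(default_factory=set)
    negative_gene_ids: set[str] = field(default_factory=set)
    linked_metabolite_ids: set[str] = field(default_factory=set)
    planted_clusters: list[tuple[str, str, tuple[str, ...]]] = field(
        default_factory=list
    )
    decoy_gene_ids: set[str] = field(default_factory=set)
    scattered_adh_gene_ids: set[str] = field(default_factory=set)
    adh_family: dict[str, str] = field(default_factory=dict)
    proteome_gene_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.module_gene_ids & self.negative_gene_ids
        if overlap:
            raise ConfigError(f"module and negative sets overlap: {sorted(overlap)[:5]}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_gene_ids": sorted(self.module_gene_ids),
            "module_adh_gene_ids": sorted(self.module_adh_gene_ids),
            "negative_gene_ids": sorted(self.negative_gene_ids),
            "linked_metabolite_ids": sorted(self.linked_metabolite_ids),
            "planted_clusters": [
                {"contig": c, "anchor": a, "members": list(m)}
                for c, a, m in self.planted_clusters
            ],
            "decoy_gene_ids": sorted(self.decoy_gene_ids),
            "scattered_adh_gene_ids": sorted(self.scattered_adh_gene_ids),
            "adh_family": dict(sorted(self.adh_family.items())),
            "proteome_gene_ids": sorted(self.proteome_gene_ids),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _gene_ids(config: SimulationConfig) -> list[str]:
    return [f"MSTRG.{i}" for i in range(1, config.n_genes + 1)]


def _assign_roles(config: SimulationConfig) -> dict[str, list[str]]:
    """Deterministically partition gene ids into ecological roles.

    Cluster-resident genes (anchors, MDR members, decoys and their contig
    neighbours) occupy the head of the id range so the genome layout can
    place them; scattered roles follow.
    """
    ids = _gene_ids(config)
    n_members = config.n_planted_clusters * config.cluster_members_per_anchor
    if n_members > config.n_module_adh:
        raise ConfigError(
            "planted cluster MDR members exceed n_module_adh; raise n_module_adh"
        )
    it = iter(ids)
    roles: dict[str, list[str]] = {
        "anchor": [next(it) for _ in range(config.n_planted_clusters)],
        "member": [next(it) for _ in range(n_members)],
        "decoy": [next(it) for _ in range(config.n_decoy_near_misses)],
    }
    n_module_rest = config.n_mia_module - config.n_planted_clusters
    if n_module_rest < 0:
        raise ConfigError("n_planted_clusters exceeds n_mia_module")
    roles["module_other"] = [next(it) for _ in range(n_module_rest)]
    roles["module_adh_other"] = [
        next(it) for _ in range(config.n_module_adh - n_members)
    ]
    roles["scattered_adh"] = [next(it) for _ in range(config.n_scattered_adh)]
    roles["negative"] = [next(it) for _ in range(config.n_negatives)]
    roles["background"] = list(it)
    return roles


# ---------------------------------------------------------------------------
# expression atlas + metabolites
# ---------------------------------------------------------------------------


def generate_atlas(config: SimulationConfig):
    """Simulate the TPM atlas, the paired metabolite matrix and labels.

    Module genes (labelled positives and unlabelled ADH targets alike) share
    one latent tissue profile on the log2 scale plus gene-specific noise;
    linked metabolites ride the same profile; negatives are flat and
    well-expressed; background genes get independent gene-by-tissue effects.
    TPM is 2**(log2 model) with no compositional renormalization, keeping
    planted correlations exact.

    Returns ``(tpm, sample_meta, metabolites, truth)`` where ``tpm`` is a
    transcripts x samples DataFrame, ``sample_meta`` indexes samples with
    tissue_type and replicate, ``metabolites`` is a raw (un-normalized)
    metabolites x samples DataFrame and ``truth`` a :class:`GroundTruth`
    carrying the atlas-level labels.
    """
    config.validate()
    rng, rng_met = _child_rngs(config.seed, 4)[:2]
    roles = _assign_roles(config)
    module = roles["anchor"] + roles["module_other"]
    module_adh = roles["member"] + roles["module_adh_other"]
    negatives = roles["negative"]
    all_module = module + module_adh

    samples = [
        f"T{t:02d}_R{k}"
        for t in range(1, config.n_tissues + 1)
        for k in range(1, config.replicates_per_tissue + 1)
    ]
    tissues = np.repeat(np.arange(config.n_tissues), config.replicates_per_tissue)
    if config.drop_samples:
        samples = samples[: len(samples) - config.drop_samples]
        tissues = tissues[: len(samples)]
    n_samples = len(samples)
    sample_meta = pd.DataFrame(
        {
            "tissue_type": [f"tissue_{t + 1:02d}" for t in tissues],
            "replicate": [int(s.split("_R")[1]) for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )

    gene_ids = _gene_ids(config)
    tx_ids = [g + ".1" for g in gene_ids]
    role_of = {}
    for role, members in roles.items():
        for g in members:
            role_of[g] = role

    latent = rng.normal(0.0, config.module_signal_sd, size=config.n_tissues)
    log2tpm = np.empty((config.n_genes, n_samples))
    module_set = set(all_module)
    negative_set = set(negatives)
    for i, g in enumerate(gene_ids):
        if g in module_set:
            base = rng.normal(
                config.module_baseline_logmean, config.module_baseline_logsd
            )
            row = base + latent[tissues] + rng.normal(
                0.0, config.module_noise_sd, n_samples
            )
        elif g in negative_set:
            base = rng.normal(
                config.module_baseline_logmean, config.module_baseline_logsd
            )
            row = base + rng.normal(0.0, config.negative_noise_sd, n_samples)
        else:
            base = rng.normal(config.baseline_logmean, config.baseline_logsd)
            per_tissue = rng.normal(0.0, config.tissue_effect_sd, config.n_tissues)
            row = base + per_tissue[tissues] + rng.normal(
                0.0, config.replicate_noise_sd, n_samples
            )
        log2tpm[i] = row
    tpm = pd.DataFrame(
        np.exp2(log2tpm), index=pd.Index(tx_ids, name="transcript"), columns=samples
    )

    met_ids = [f"metab_{i:02d}" for i in range(1, config.n_metabolites + 1)]
    linked = met_ids[: config.n_metabolites_linked]
    met = np.empty((config.n_metabolites, n_samples))
    for i, m in enumerate(met_ids):
        base = rng_met.normal(8.0, 1.0)
        if m in linked:
            row = base + latent[tissues] + rng_met.normal(0.0, 0.4, n_samples)
        else:
            per_tissue = rng_met.normal(0.0, config.tissue_effect_sd, config.n_tissues)
            row = base + per_tissue[tissues] + rng_met.normal(0.0, 0.4, n_samples)
        met[i] = row
    metabolites = pd.DataFrame(
        np.exp2(met), index=pd.Index(met_ids, name="metabolite"), columns=samples
    )

    truth = GroundTruth(
        module_gene_ids=set(module),
        module_adh_gene_ids=set(module_adh),
        negative_gene_ids=set(negatives),
        linked_metabolite_ids=set(linked),
    )
    return tpm, sample_meta, metabolites, truth


# ---------------------------------------------------------------------------
# genome layout, domains, BLAST hits
# ---------------------------------------------------------------------------


def generate_genome_layout(config: SimulationConfig):
    """Lay genes along toy contigs and plant recoverable clusters plus decoys.

    Each planted cluster is an anchor gene whose BLAST hit passes the
    90% coverage / 60% identity assignment rule, followed by whitelist-Pfam
    MDR neighbours placed at fixed gaps so the whole cluster sits inside
    ``cluster_span_bp`` (< 2 x scan window).  Each decoy carries a whitelist
    domain but is placed 100,001-150,000 bp downstream of its anchor span,
    just beyond the window.  Gene spans never overlap within a contig.

    Returns ``(genes, domains, hits, truth)``.
    """
    config.validate()
    rng = _child_rngs(config.seed, 4)[2]
    roles = _assign_roles(config)

    genes: list[GeneModel] = []
    truth = GroundTruth()
    anchors = list(roles["anchor"])
    members = list(roles["member"])
    decoys = list(roles["decoy"])
    k = config.cluster_members_per_anchor

    # Remaining ids fill contigs in order.  Domain-free roles (negatives,
    # background) go first so that no whitelist-domain gene can land on a
    # cluster contig near a planted anchor by accident.
    filler = (
        roles["negative"]
        + roles["background"]
        + roles["module_other"]
        + roles["module_adh_other"]
        + roles["scattered_adh"]
    )
    filler_it = iter(filler)

    def draw_len() -> int:
        return int(rng.uniform(0.5, 1.5) * config.mean_gene_len)

    def draw_gap() -> int:
        return int(rng.uniform(0.5, 1.5) * config.mean_intergenic)

    per_contig = config.genes_per_contig
    for c in range(config.n_contigs):
        contig = f"ctg{c + 1}"
        pos = 1 + draw_gap()
        placed = 0
        cluster_here = c < config.n_planted_clusters
        # a few ordinary genes before the planted stretch
        n_prefix = int(rng.integers(3, 8)) if cluster_here else 0
        anchor_gene = None
        member_genes: list[GeneModel] = []

        def place(gene_id: str, length: int | None = None) -> GeneModel:
            nonlocal pos, placed
            length = draw_len() if length is None else length
            gm = GeneModel(
                gene_id=gene_id,
                transcript_ids=(gene_id + ".1",),
                contig=contig,
                start=pos,
                end=pos + length - 1,
                strand="+" if rng.random() < 0.5 else "-",
            )
            genes.append(gm)
            pos = gm.end + 1 + draw_gap()
            placed += 1
            return gm

        if cluster_here:
            for _ in range(n_prefix):
                place(next(filler_it))
            anchor_gene = place(anchors[c], length=config.mean_gene_len)
            # fixed-pitch members guarantee the planted geometry
            for m in range(k):
                pos = anchor_gene.end + (m + 1) * (
                    config.mean_gene_len + config.mean_intergenic
                ) - config.mean_gene_len + 1
                gm = GeneModel(
                    gene_id=members[c * k + m],
                    transcript_ids=(members[c * k + m] + ".1",),
                    contig=contig,
                    start=pos,
                    end=pos + config.mean_gene_len - 1,
                    strand="+",
                )
                genes.append(gm)
                member_genes.append(gm)
                placed += 1
            pos = member_genes[-1].end + 1 + draw_gap()
            if c < len(decoys):
                # near miss: gap to the anchor span in (window, window + 50 kb]
                gap = int(config.scan_window + rng.integers(1000, 50000))
                pos = anchor_gene.end + gap + 1
                place(decoys[c], length=config.mean_gene_len)
            truth.planted_clusters.append(
                (contig, anchor_gene.gene_id, tuple(g.gene_id for g in member_genes))
            )
        while placed < per_contig:
            try:
                place(next(filler_it))
            except StopIteration:
                break

    leftover = list(filler_it)
    if leftover:  # spill onto one extra contig rather than dropping genes
        contig = f"ctg{config.n_contigs + 1}"
        pos = 1
        for g in leftover:
            length = draw_len()
            genes.append(
                GeneModel(g, (g + ".1",), contig, pos, pos + length - 1, "+")
            )
            pos += length + draw_gap()

    truth.decoy_gene_ids = set(decoys[: config.n_planted_clusters])
    truth.module_gene_ids = set(roles["anchor"] + roles["module_other"])
    truth.module_adh_gene_ids = set(members + roles["module_adh_other"])
    truth.negative_gene_ids = set(roles["negative"])
    truth.scattered_adh_gene_ids = set(roles["scattered_adh"])

    # --- domains -----------------------------------------------------------
    domains: list[DomainAnnotation] = []

    def add_adh(gene_id: str, family: str) -> None:
        truth.adh_family[gene_id] = family
        if family == "MDR":
            domains.append(DomainAnnotation(gene_id, MDR_PFAM[0], "ADH_zinc_N"))
            domains.append(DomainAnnotation(gene_id, MDR_PFAM[1], "ADH_N_GroES"))
        elif family == "SDR":
            domains.append(DomainAnnotation(gene_id, SDR_PFAM, "adh_short"))
        else:
            domains.append(DomainAnnotation(gene_id, AKR_PFAM, "Aldo_ket_red"))

    for g in members:  # planted cluster neighbours are module MDRs
        add_adh(g, "MDR")
    other_adh = roles["module_adh_other"]
    n_sdr = (2 * len(other_adh)) // 3
    for g in other_adh[:n_sdr]:
        add_adh(g, "SDR")
    for g in other_adh[n_sdr:]:
        add_adh(g, "AKR")
    fam_cycle = ["MDR", "SDR", "SDR", "AKR"]
    for i, g in enumerate(roles["scattered_adh"]):
        add_adh(g, fam_cycle[i % len(fam_cycle)])
    for g in truth.decoy_gene_ids:
        domains.append(DomainAnnotation(g, _DECOY_PFAM, "p450"))
    n_filler_dom = max(0, config.n_genes // 10)
    filler_pool = roles["background"]
    if filler_pool:
        chosen = rng.choice(len(filler_pool), min(n_filler_dom, len(filler_pool)),
                            replace=False)
        for idx in sorted(chosen):
            g = filler_pool[idx]
            acc = _FILLER_PFAMS[int(rng.integers(len(_FILLER_PFAMS)))]
            domains.append(DomainAnnotation(g, acc, "other"))

    # --- BLAST hits vs known MIA proteins ----------------------------------
    hits: list[BlastHit] = []
    subjects = ["STR", "SGD", "TDC", "GS", "THAS1", "HYS", "SAT", "T3O"]
    if config.n_planted_clusters > 0:
        for i, g in enumerate(anchors):
            hits.append(
                BlastHit(
                    query_id=g,
                    subject_id=subjects[i % len(subjects)],
                    percent_identity=float(rng.uniform(75, 98)),
                    coverage=float(rng.uniform(92, 100)),
                    evalue=1e-50,
                    bitscore=float(rng.uniform(300, 600)),
                )
            )
    for g in roles["module_other"]:
        # homologous but failing the 90/60 assignment rule, so the gene is a
        # labelled positive without anchoring a physical cluster
        if rng.random() < 0.5:
            pident, cov = float(rng.uniform(40, 58)), float(rng.uniform(91, 99))
        else:
            pident, cov = float(rng.uniform(62, 90)), float(rng.uniform(40, 85))
        hits.append(
            BlastHit(
                query_id=g,
                subject_id=subjects[int(rng.integers(len(subjects)))],
                percent_identity=pident,
                coverage=cov,
                evalue=float(10.0 ** -rng.uniform(10, 40)),
                bitscore=float(rng.uniform(80, 250)),
            )
        )
    return genes, domains, hits, truth


# ---------------------------------------------------------------------------
# GO table + latex proteome
# ---------------------------------------------------------------------------


def generate_go_and_proteome(config: SimulationConfig, truth: GroundTruth):
    """Assign GO terms and pick the latex-proteome gene list.

    A configured fraction of ADH-domain genes receive the oxidoreductase
    term GO:0016491; the proteome is a fixed-size gene list containing a
    configured share of the module ADHs plus scattered ADHs and background
    filler.  Returns ``(go_table, proteome)`` with ``go_table`` a dict
    gene_id -> set of GO ids.
    """
    config.validate()
    rng = _child_rngs(config.seed, 4)[3]
    go_table: dict[str, set[str]] = {}
    adh_genes = sorted(truth.adh_family)
    for g in adh_genes:
        if rng.random() < config.go_oxidoreductase_fraction:
            term = GO_OXIDOREDUCTASE if rng.random() < 0.5 else GO_OXIDATION_REDUCTION
            go_table.setdefault(g, set()).add(term)
        go_table.setdefault(g, set()).add(_FILLER_GO[0])
    others = sorted(
        (truth.module_gene_ids | truth.negative_gene_ids) - set(adh_genes)
    )
    for g in others:
        if rng.random() < 0.3:
            go_table.setdefault(g, set()).add(
                _FILLER_GO[int(rng.integers(1, len(_FILLER_GO)))]
            )

    proteome: list[str] = []
    module_adh = sorted(truth.module_adh_gene_ids)
    for g in module_adh:
        if rng.random() < config.proteome_adh_inclusion:
            proteome.append(g)
    scattered = sorted(truth.scattered_adh_gene_ids)
    n_scatter = min(len(scattered), max(0, config.proteome_size // 6))
    if n_scatter:
        idx = rng.choice(len(scattered), n_scatter, replace=False)
        proteome.extend(scattered[i] for i in sorted(idx))
    pool = sorted(truth.negative_gene_ids | truth.module_gene_ids)
    while len(proteome) < config.proteome_size and pool:
        g = pool[int(rng.integers(len(pool)))]
        if g not in proteome:
            proteome.append(g)
    proteome = proteome[: config.proteome_size]
    truth.proteome_gene_ids = set(proteome)
    return go_table, proteome


# ---------------------------------------------------------------------------
# whole-study orchestration
# ---------------------------------------------------------------------------


@dataclass
class SyntheticStudy:
    """All generated artefacts of one simulated study, in memory."""

    config: SimulationConfig
    tpm: pd.DataFrame
    sample_meta: pd.DataFrame
    metabolites: pd.DataFrame
    genes: list[GeneModel]
    domains: list[DomainAnnotation]
    hits: list[BlastHit]
    go_table: dict[str, set[str]]
    proteome: list[str]
    truth: GroundTruth

    @property
    def labels(self) -> dict[str, list[str]]:
        """Transcript-level label lists (positives / negatives / unlabelled)."""
        pos = sorted(g + ".1" for g in self.truth.module_gene_ids)
        neg = sorted(g + ".1" for g in self.truth.negative_gene_ids)
        labelled = set(pos) | set(neg)
        unl = sorted(t for t in self.tpm.index if t not in labelled)
        return {"positives": pos, "negatives": neg, "unlabeled": unl}


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate every pipeline input for one seeded study."""
    tpm, sample_meta, metabolites, atlas_truth = generate_atlas(config)
    genes, domains, hits, truth = generate_genome_layout(config)
    truth.linked_metabolite_ids = atlas_truth.linked_metabolite_ids
    go_table, proteome = generate_go_and_proteome(config, truth)
    return SyntheticStudy(
        config, tpm, sample_meta, metabolites, genes, domains, hits,
        go_table, proteome, truth,
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write all study files with deterministic formatting; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "atlas": outdir / "atlas.tsv",
        "meta": outdir / "sample_meta.tsv",
        "metabolites": outdir / "metabolites.tsv",
        "genes": outdir / "genes.gff3",
        "domains": outdir / "domains.tsv",
        "hits": outdir / "mia_hits.tsv",
        "go": outdir / "go.tsv",
        "proteome": outdir / "latex_proteome.txt",
        "labels": outdir / "labels.json",
        "truth": outdir / "ground_truth.json",
    }
    write_matrix(study.tpm, paths["atlas"])
    study.sample_meta.to_csv(paths["meta"], sep="\t")
    write_matrix(study.metabolites, paths["metabolites"])
    write_gene_models(study.genes, paths["genes"])
    write_domain_table(study.domains, paths["domains"])
    write_blast_tab(study.hits, paths["hits"])
    with open(paths["go"], "w") as fh:
        for g in sorted(study.go_table):
            for term in sorted(study.go_table[g]):
                fh.write(f"{g}\t{term}\n")
    paths["proteome"].write_text("".join(g + "\n" for g in study.proteome))
    with open(paths["labels"], "w") as fh:
        json.dump(study.labels, fh, indent=1)
    study.truth.to_json(paths["truth"])
    return paths
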