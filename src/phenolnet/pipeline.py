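"""End-to-end pipeline: one YAML config chaining all analysis stages.

Stage order: co-expression network → lncRNA co-location → miRNA targets →
promoter CRE enrichment → multilayer integration. Every stage reads its
inputs from disk and writes its outputs to the run directory, so stages can
be re-run idempotently. A run manifest records the package version, the
full parameter set, SHA-256 checksums of every input and output, and the
seed; reruns with identical inputs and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq

from . import __version__
from .colocation import ColocationConfig, classify_lncrna, lncrna_edges, pairs_to_frame, parse_features
from .gcn import NetworkConfig, build_network, compute_pcc_matrix, edges_to_frame, filter_dynamic_genes, load_expression
from .integrate import assemble, centrality_report, detect_modules, export, extract_subnetwork
from .mirna import ScoringScheme, duplexes_to_frame, mirna_edges, predict_targets
from .motifs import DEFAULT_MOTIFS, annotate_presence, enrich_modules, enrichment_to_frame, extract_promoters, hits_to_frame, load_motifs, scan_motifs

logger = logging.getLogger(__name__)

STAGES = ["gcn", "colocation", "mirna_target", "cre_enrichment", "integrate"]


@dataclass
class PipelineConfig:
    """All inputs, outputs, and stage parameters of one pipeline run."""

    expression: str
    gff: str
    genome_fasta: str
    transcripts: str
    mirnas: str
    tx2gene: str | None = None
    motifs: str | None = None
    tf_list: str | None = None
    pathway: str | None = None
    out_dir: str = "phenolnet_out"
    gene_filter: dict | None = None
    network: dict = field(default_factory=dict)
    colocation: dict = field(default_factory=dict)
    scoring: dict = field(default_factory=dict)
    promoter_length: int = 2000
    module_method: str = "positive_components"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        base = Path(path).parent
        for attr in ("expression", "gff", "genome_fasta", "transcripts",
                     "mirnas", "tx2gene", "motifs", "tf_list", "pathway"):
            val = getattr(cfg, attr)
            if val is not None and not Path(val).is_absolute():
                setattr(cfg, attr, str(base / val))
        return cfg

    def validate(self) -> None:
        for attr in ("expression", "gff", "genome_fasta", "transcripts",
                     "mirnas", "tx2gene", "motifs", "tf_list", "pathway"):
            val = getattr(self, attr)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"{attr}: {val} does not exist")
        NetworkConfig(**self.network)
        ColocationConfig(**self.colocation)
        ScoringScheme(**self.scoring)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_lines(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def _genome_dict(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages and return the output directory.

    Any stage failure raises with the stage name prepended. The manifest
    (``manifest.json``) is written last; it contains no timestamps so that
    reruns with the same inputs and seed are byte-identical.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "phenolnet",
        "version": __version__,
        "seed": config.seed,
        "parameters": {k: v for k, v in asdict(config).items()},
        "stages": [],
        "inputs": {},
        "outputs": {},
    }
    for attr in ("expression", "gff", "genome_fasta", "transcripts",
                 "mirnas", "tx2gene", "motifs", "tf_list", "pathway"):
        val = getattr(config, attr)
        if val is not None:
            manifest["inputs"][attr] = _sha256(val)

    stage = "gcn"
    try:
        m = load_expression(config.expression)
        if config.gene_filter:
            m = filter_dynamic_genes(m, config.gene_filter)
        net_cfg = NetworkConfig(**config.network)
        corr = compute_pcc_matrix(m, transform=net_cfg.transform)
        features = parse_features(config.gff)
        lnc_ids = {f.id for f in features if f.kind == "lncRNA"}
        gene_corr = corr.drop(index=[g for g in corr.index if g in lnc_ids],
                              columns=[g for g in corr.columns if g in lnc_ids])
        gcn_edge_list = build_network(gene_corr, net_cfg)
        edges_to_frame(gcn_edge_list).to_csv(out / "gcn_edges.tsv", sep="\t", index=False)
        manifest["stages"].append(stage)

        stage = "colocation"
        coloc_cfg = ColocationConfig(**config.colocation)
        genes = [f for f in features if f.kind == "gene"]
        lncs = [f for f in features if f.kind == "lncRNA"]
        pairs = lncrna_edges(lncs, genes, corr, coloc_cfg)
        pairs_to_frame(pairs).to_csv(out / "lncrna_pairs.tsv", sep="\t", index=False)
        classes = pd.DataFrame(
            [(l.id, classify_lncrna(l, genes)) for l in sorted(lncs, key=lambda f: f.id)],
            columns=["lncrna", "class"],
        )
        classes.to_csv(out / "lncrna_classes.tsv", sep="\t", index=False)
        manifest["stages"].append(stage)

        stage = "mirna_target"
        scheme = ScoringScheme(**config.scoring)
        duplexes = predict_targets(str(config.mirnas), str(config.transcripts), scheme)
        duplexes_to_frame(duplexes).to_csv(out / "mirna_duplexes.tsv", sep="\t", index=False)
        if config.tx2gene:
            t2g = pd.read_csv(config.tx2gene, sep="\t", header=None,
                              names=["transcript", "gene"])
            gene_map = dict(zip(t2g["transcript"], t2g["gene"]))
        else:
            gene_map = {}
        mir_edges = mirna_edges(duplexes, gene_map)
        mir_edges.to_csv(out / "mirna_edges.tsv", sep="\t", index=False)
        manifest["stages"].append(stage)

        stage = "cre_enrichment"
        motif_set = load_motifs(config.motifs) if config.motifs else list(DEFAULT_MOTIFS)
        genome = _genome_dict(config.genome_fasta)
        promoters = extract_promoters(genes, genome, config.promoter_length)
        hits = scan_motifs(promoters, motif_set)
        hits_to_frame(hits).to_csv(out / "motif_hits.tsv", sep="\t", index=False)
        presence = annotate_presence(hits, sorted(promoters), [m.name for m in motif_set])
        presence.to_csv(out / "motif_presence.tsv", sep="\t", index_label="gene_id")
        manifest["stages"].append(stage)

        stage = "integrate"
        tfs = _read_lines(config.tf_list) if config.tf_list else []
        annotations = {
            gid: {m: bool(presence.loc[gid, m]) for m in presence.columns}
            for gid in presence.index
        }
        net = assemble(gcn_edge_list, tfs, pairs, mir_edges, annotations)
        partition = detect_modules(net, config.module_method, config.seed)
        pd.DataFrame(
            sorted(partition.labels.items()), columns=["node", "module"]
        ).to_csv(out / "modules.tsv", sep="\t", index=False)
        # motif enrichment per detected module, over gene-type nodes with promoters
        modules: dict[str, list[str]] = {}
        for node, label in partition.labels.items():
            if node in presence.index:
                modules.setdefault(label, []).append(node)
        enr = enrich_modules(presence, modules, background=sorted(presence.index))
        enrichment_to_frame(enr).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        centrality_report(net).to_csv(out / "centrality.tsv", sep="\t")
        export(net, "graphml", out / "network.graphml")
        export(net, "sif", out / "network.sif")
        export(net, "tsv", out / "network")
        if config.pathway:
            pathway = _read_lines(config.pathway)
            sub = extract_subnetwork(net, pathway, include_regulators=True)
            export(sub, "graphml", out / "subnetwork.graphml")
            centrality_report(sub).to_csv(out / "subnetwork_centrality.tsv", sep="\t")
        manifest["stages"].append(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def extract_transcripts(genes, genome: dict[str, str]) -> list[tuple[str, str]]:
    """Gene-body sequences (strand-aware) used as stand-in transcripts."""
    out = []
    for g in sorted(genes, key=lambda f: f.id):
        seq = genome[g.chrom][g.start:g.end]
        if g.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        out.append((g.id, seq))
    return out


def write_fixture_suite(out_dir, seed: int = 0) -> Path:
    """Generate the complete synthetic input suite plus a ready pipeline config.

    Layout: expression.tsv, genome.gff3, genome.fa, transcripts.fa,
    tx2gene.tsv, mirnas.fa, mirna_truth.tsv, motifs.tsv, tf_list.txt,
    pathway.txt, config.yaml. The genome realizes the tandem-cluster and
    antisense-lncRNA landmarks; the MYB CCWACC site is planted in the
    promoters of the tandem-cluster and early-phenylpropanoid genes and
    scrubbed from all other promoters, so enrichment ground truth is exact.
    """
    from .motifs import Motif
    from .simulate import (PlantedModule, SimulationDesign, default_genome_spec,
                           simulate_expression, simulate_genome, simulate_mirna_pairs)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = default_genome_spec()
    sts = [f"STS{i:02d}" for i in range(1, 10)]
    myb = Motif("MYB_CCWACC", "CCWACC", "R2R3-MYB")
    promoter_length = 500
    gff3, fasta = simulate_genome(
        spec, seed=seed, planted_motif=myb,
        motif_gene_ids=sts + ["PAL1", "PAL2", "C4H1"],
        promoter_length=promoter_length,
    )
    (out / "genome.gff3").write_text(gff3)
    (out / "genome.fa").write_text(fasta)

    design = SimulationDesign(
        modules=[
            PlantedModule("mod_ripening", sts + ["lnc_STS_cluster", "PAL1", "PAL2",
                                                 "C4H1", "MYB14", "WRKY03"],
                          base_profile="ripening_up"),
            PlantedModule("mod_early", ["GGT1", "lnc_antisense", "CHS1", "CHI1", "F3H1"],
                          base_profile="early_up"),
            PlantedModule("mod_mid", ["FAR1"], base_profile="mid_peak"),
        ],
        n_background=20,
        seed=seed,
    )
    simulate_expression(design).to_tsv(out / "expression.tsv")

    genome = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(out / "genome.fa"), "fasta")}
    transcripts = extract_transcripts(spec.genes(), genome)
    with open(out / "transcripts.fa", "w") as fh:
        for tid, seq in transcripts:
            fh.write(f">{tid}\n{seq}\n")
    pd.DataFrame([(t, t) for t, _ in transcripts]).to_csv(
        out / "tx2gene.tsv", sep="\t", header=False, index=False
    )
    mirna_fa, truth = simulate_mirna_pairs(
        transcripts, n_pairs=3, mismatches=1, wobbles=1, seed=seed + 1
    )
    (out / "mirnas.fa").write_text(mirna_fa)
    truth.to_csv(out / "mirna_truth.tsv", sep="\t", index=False)

    motif_rows = [(m.name, m.iupac, m.tf_family) for m in DEFAULT_MOTIFS]
    pd.DataFrame(motif_rows, columns=["name", "iupac", "family"]).to_csv(
        out / "motifs.tsv", sep="\t", index=False
    )
    (out / "tf_list.txt").write_text("MYB14\nWRKY03\n")
    pathway = sts + ["PAL1", "PAL2", "C4H1", "GGT1", "CHS1", "CHI1", "F3H1"]
    (out / "pathway.txt").write_text("\n".join(pathway) + "\n")

    cfg = {
        "expression": "expression.tsv",
        "gff": "genome.gff3",
        "genome_fasta": "genome.fa",
        "transcripts": "transcripts.fa",
        "mirnas": "mirnas.fa",
        "tx2gene": "tx2gene.tsv",
        "motifs": "motifs.tsv",
        "tf_list": "tf_list.txt",
        "pathway": "pathway.txt",
        "out_dir": str(out / "results"),
        "network": {"pcc_threshold": 0.8, "transform": "log2"},
        "colocation": {"window_bp": 100000, "pcc_threshold": 0.8},
        "scoring": {"max_expectation": 3.0},
        "promoter_length": promoter_length,
        "module_method": "positive_components",
        "seed": seed,
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return out
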