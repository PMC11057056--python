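"""End-to-end orchestration of the analysis stages on a working directory,
with YAML config, checksum-based stage caching and a run report.

Stage order: simulate -> reconcile -> orthofilter -> codonalign -> selscan
-> profile -> cluster -> electro.  Each stage reads files written by
earlier stages, so a manifest of input/output checksums lets unchanged
stages be served from cache and corrupted intermediates be detected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, chem, cluster, electro, io, orthofilter, selection, synthetic
from .codonalign import strip_gap_columns
from .orthofilter import Orthogroup, OrthoMember
from .trees import SpeciesTree

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "reconcile", "orthofilter", "codonalign",
    "selscan", "profile", "cluster", "electro",
)


@dataclass
class PipelineConfig:
    workdir: str = "sawselect_run"
    seed: int = 1
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # thresholds (defaults are the analysis' own operating points)
    min_mapq: int = 10
    cov_threshold: int = 5
    max_delta_aa: int = 100
    min_codons: int = 20
    alpha: float = 0.05
    omega_cap: float = 10_000.0
    k: int = 2
    n_init: int = 25
    focal_taxon: str = "P_pectinata"
    reference_taxon: str = "L_erinacea"
    # synthetic demo sizes
    n_genes: int = 8
    n_selected: int = 2
    n_codons_per_gene: int = 200
    n_orthogroups: int = 40
    selected_omega: float = 9.0
    selected_weight: float = 0.3

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class RunReport:
    completed: list[str] = field(default_factory=list)
    cached: list[str] = field(default_factory=list)
    outputs: dict[str, list[str]] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineRunner:
    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.root = Path(config.workdir)
        self.inputs = self.root / "inputs"
        self.outdir = self.root / "outputs"
        self.manifest_path = self.root / "manifest.json"
        self.manifest: dict = {}
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())

    # -- caching ----------------------------------------------------------

    def _stage_fresh(self, stage: str, input_paths: list[Path]) -> bool:
        entry = self.manifest.get(stage)
        if entry is None:
            return False
        recorded_inputs = entry.get("inputs", {})
        if {str(p) for p in input_paths} != set(recorded_inputs):
            return False
        for p_str, digest in recorded_inputs.items():
            p = Path(p_str)
            if not p.exists() or _sha256(p) != digest:
                return False
        for p_str, digest in entry.get("outputs", {}).items():
            p = Path(p_str)
            if not p.exists():
                return False
            if _sha256(p) != digest:
                raise RuntimeError(
                    f"stage {stage!r}: cached output {p_str} fails its checksum "
                    "(corrupted intermediate)"
                )
        return True

    def _record(self, stage: str, input_paths: list[Path], output_paths: list[Path]) -> None:
        self.manifest[stage] = {
            "inputs": {str(p): _sha256(p) for p in input_paths},
            "outputs": {str(p): _sha256(p) for p in output_paths},
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1))

    # -- stages -----------------------------------------------------------

    def run(self) -> RunReport:
        report = RunReport()
        self.root.mkdir(parents=True, exist_ok=True)
        self.cfg.to_yaml(self.root / "resolved_config.yaml")
        for stage in STAGES:
            if stage not in self.cfg.stages:
                continue
            inputs, run_fn = getattr(self, f"_plan_{stage}")()
            try:
                fresh = self._stage_fresh(stage, inputs)
            except RuntimeError:
                raise
            if fresh:
                logger.info("stage %s: served from cache", stage)
                report.cached.append(stage)
                report.outputs[stage] = sorted(self.manifest[stage]["outputs"])
                continue
            outputs = run_fn()
            self._record(stage, inputs, outputs)
            report.completed.append(stage)
            report.outputs[stage] = [str(p) for p in outputs]
        return report

    # each _plan_<stage> returns (input paths, runner closure -> output paths)

    def _plan_simulate(self):
        def run() -> list[Path]:
            cfg = self.cfg
            self.inputs.mkdir(parents=True, exist_ok=True)
            rng = np.random.default_rng(cfg.seed)
            tree = SpeciesTree.default_five_taxon()
            (self.inputs / "species_tree.nwk").write_text(tree.to_newick() + "\n")
            focal = tree.tip_id(cfg.focal_taxon)
            genes_dir = io.ensure_dir(self.inputs / "genes")
            truth = {"seed": cfg.seed, "selected_genes": [], "genes": {}}
            for g in range(cfg.n_genes):
                gid = f"gene{g:03d}"
                selected = g < cfg.n_selected
                mixtures = (
                    {focal: [(synthetic.DEFAULT_BACKGROUND_OMEGA, 1.0 - cfg.selected_weight),
                             (cfg.selected_omega, cfg.selected_weight)]}
                    if selected else {}
                )
                sim = synthetic.SimulationConfig(
                    tree=tree,
                    params=synthetic.CodonModelParams(branch_mixtures=mixtures),
                    n_sites=cfg.n_codons_per_gene,
                    seed=int(rng.integers(2**31 - 1)),
                )
                aln = synthetic.simulate_codon_alignment(sim)
                (genes_dir / f"{gid}.fasta").write_text(aln.to_fasta())
                truth["genes"][gid] = {"selected": selected, "seed": sim.seed}
                if selected:
                    truth["selected_genes"].append(gid)
            # toy contig with a low-coverage region and an exon-skipping locus
            records = synthetic.simulate_read_alignments(
                contig_length=1000,
                intervals_with_depth=[(0, 300, 8), (300, 400, 3), (400, 600, 12)],
                junction_spec=[
                    synthetic.JunctionSpec((600, 700), (720, 780), count=7),
                    synthetic.JunctionSpec((720, 780), (800, 850), count=4),
                    synthetic.JunctionSpec((600, 700), (800, 850), count=3),
                ],
                seed=cfg.seed,
            )
            io.write_block_tsv(records, self.inputs / "reads.tsv")
            # intervals the exon-retention call needs
            (self.inputs / "splice_model.json").write_text(json.dumps({
                "contig": "contig1", "contig_length": 1000,
                "upstream": [600, 700], "exon": [720, 780], "downstream": [800, 850],
            }))
            groups = synthetic.simulate_orthogroup_collection(
                n_groups=cfg.n_orthogroups,
                taxa=tuple(tree.tip_names),
                paralog_rate=0.2, length_outlier_rate=0.2, missing_taxon_rate=0.2,
                seed=cfg.seed + 1,
            )
            rows = []
            for grp in groups:
                for m in grp.members:
                    rows.append({
                        "group_id": grp.group_id, "taxon": m.taxon, "seq_id": m.seq_id,
                        "annotation": m.annotation, "protein": m.protein, "cds": m.cds,
                        **{f"truth_{k}": v for k, v in grp.ground_truth.items()},
                    })
            pd.DataFrame(rows).to_csv(self.inputs / "orthogroups.tsv", sep="\t", index=False)
            # channel panel for the electrosensory stage
            channels = {
                "Kcnma1_Ppec": "MSNLS" + "TVGYG" + "LRMLI" * 6,
                "Kv1_Ppec": "MAGLY" + "TVGYG" + "DMLPA" * 6,
                "Cacnb2_Ppec": "MVQSD" + "PLEAR" * 7,
            }
            io.write_fasta(channels, self.inputs / "channels.fasta")
            pd.DataFrame({
                "transcript_id": list(channels),
                "tissue": ["rostral_skin"] * 3,
                "count": [900, 140, 0],
                "length_nt": [3600, 1500, 1800],
                "total_mapped": [2_000_000] * 3,
            }).to_csv(self.inputs / "expression_counts.tsv", sep="\t", index=False)
            terms = {
                "GO:morphogenesis": truth["selected_genes"]
                + [f"gene{g:03d}" for g in range(cfg.n_selected, min(cfg.n_selected + 2, cfg.n_genes))],
                "GO:transport": [f"gene{g:03d}" for g in range(cfg.n_genes) if g % 3 == 0],
            }
            (self.inputs / "go_terms.json").write_text(json.dumps(terms, indent=1))
            (self.inputs / "ground_truth.json").write_text(json.dumps(truth, indent=1))
            return sorted(self.inputs.rglob("*.*"))

        return [], run

    def _plan_reconcile(self):
        reads = self.inputs / "reads.tsv"

        def run() -> list[Path]:
            out = io.ensure_dir(self.outdir / "reconcile")
            records = io.read_block_tsv(reads)
            coverage = annotation.compute_coverage(
                records, {"contig1": 1000}, min_mapq=self.cfg.min_mapq
            )
            low = annotation.low_coverage_regions(
                coverage["contig1"], threshold=self.cfg.cov_threshold, contig="contig1"
            )
            io.write_bed(low, out / "low_coverage.bed")
            np.savetxt(out / "coverage.tsv", coverage["contig1"], fmt="%d")
            return [out / "low_coverage.bed", out / "coverage.tsv"]

        return [reads], run

    def _plan_orthofilter(self):
        src = self.inputs / "orthogroups.tsv"

        def run() -> list[Path]:
            out = io.ensure_dir(self.outdir / "orthofilter")
            df = pd.read_csv(src, sep="\t")
            groups = []
            for gid, sub in df.groupby("group_id", sort=True):
                members = [
                    OrthoMember(taxon=r.taxon, seq_id=r.seq_id, protein=r.protein,
                                cds=r.cds, annotation=r.annotation)
                    for r in sub.itertuples()
                ]
                truth = {
                    k.removeprefix("truth_"): bool(sub.iloc[0][k])
                    for k in df.columns if k.startswith("truth_")
                }
                groups.append(Orthogroup(group_id=str(gid), members=members, ground_truth=truth))
            report = orthofilter.curate_orthogroups(
                groups,
                required_taxa=tuple(SpeciesTree.default_five_taxon().tip_names),
                max_delta_aa=self.cfg.max_delta_aa,
            )
            pd.DataFrame({
                "metric": ["input_groups", "failed_taxon_coverage", "split_into",
                            "failed_post_split_coverage", "members_removed_by_length",
                            "surviving"],
                "value": [report.input_groups, report.failed_taxon_coverage,
                          report.split_into, report.failed_post_split_coverage,
                          report.members_removed_by_length, len(report.surviving)],
            }).to_csv(out / "curation_report.tsv", sep="\t", index=False)
            pd.DataFrame({
                "group_id": [g.group_id for g in report.surviving]
            }).to_csv(out / "surviving_groups.tsv", sep="\t", index=False)
            return [out / "curation_report.tsv", out / "surviving_groups.tsv"]

        return [src], run

    def _gene_paths(self) -> list[Path]:
        return sorted((self.inputs / "genes").glob("*.fasta"))

    def _plan_codonalign(self):
        gene_paths = self._gene_paths() if (self.inputs / "genes").exists() else []

        def run() -> list[Path]:
            out = io.ensure_dir(self.outdir / "codonalign")
            kept = []
            for p in self._gene_paths():
                from .codonalign import CodonAlignment

                seqs = io.read_fasta(p)
                aln = CodonAlignment(ids=list(seqs), rows=list(seqs.values()))
                aln = strip_gap_columns(aln)
                if orthofilter.min_alignment_length_filter(aln, self.cfg.min_codons):
                    dest = out / p.name
                    dest.write_text(aln.to_fasta())
                    kept.append(dest)
            return kept

        return gene_paths, run

    def _plan_selscan(self):
        aln_dir = self.outdir / "codonalign"
        gene_paths = sorted(aln_dir.glob("*.fasta")) if aln_dir.exists() else []

        def run() -> list[Path]:
            from .codonalign import CodonAlignment

            out = io.ensure_dir(self.outdir / "selscan")
            tree = SpeciesTree.from_newick((self.inputs / "species_tree.nwk").read_text())
            results = []
            for p in sorted((self.outdir / "codonalign").glob("*.fasta")):
                seqs = io.read_fasta(p)
                aln = CodonAlignment(ids=list(seqs), rows=list(seqs.values()))
                results.extend(selection.test_gene(p.stem, aln, tree,
                                                   omega_cap=self.cfg.omega_cap))
            selection.correct_results(results)
            df = pd.DataFrame([dataclasses.asdict(r) for r in results])
            df.to_csv(out / "branch_tests.tsv", sep="\t", index=False)
            calls = selection.call_psgs(results, self.cfg.focal_taxon, alpha=self.cfg.alpha)
            pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(
                out / "psg_calls.tsv", sep="\t", index=False
            )
            per_gene = {
                r.gene_id: {} for r in results
            }
            for r in results:
                per_gene[r.gene_id][r.branch_name] = {
                    "lrt": r.lrt, "p": r.p_value, "corrected_p": r.corrected_p,
                    "omega2": r.omega2, "weight2": r.weight2,
                }
            (out / "branch_tests.json").write_text(json.dumps(per_gene, indent=1))
            return [out / "branch_tests.tsv", out / "psg_calls.tsv", out / "branch_tests.json"]

        return gene_paths, run

    def _plan_profile(self):
        aln_dir = self.outdir / "codonalign"
        gene_paths = sorted(aln_dir.glob("*.fasta")) if aln_dir.exists() else []

        def run() -> list[Path]:
            from .codonalign import CodonAlignment

            out = io.ensure_dir(self.outdir / "profile")
            rows = []
            for p in sorted((self.outdir / "codonalign").glob("*.fasta")):
                seqs = io.read_fasta(p)
                aln = CodonAlignment(ids=list(seqs), rows=list(seqs.values()))
                idx = {t: i for i, t in enumerate(aln.taxa)}
                from .codonalign import _translate_cds

                focal = _translate_cds(aln.rows[idx[self.cfg.focal_taxon]])
                ref = _translate_cds(aln.rows[idx[self.cfg.reference_taxon]])
                rows.append({
                    "gene_id": p.stem,
                    "gravy_focal": chem.gravy(focal),
                    "gravy_reference": chem.gravy(ref),
                    "delta_gravy": chem.gravy(focal) - chem.gravy(ref),
                })
            pd.DataFrame(rows).to_csv(out / "gravy.tsv", sep="\t", index=False)
            return [out / "gravy.tsv"]

        return gene_paths, run

    def _plan_cluster(self):
        deps = [self.outdir / "selscan" / "psg_calls.tsv", self.outdir / "profile" / "gravy.tsv"]
        deps = [d for d in deps if d.exists()]

        def run() -> list[Path]:
            out = io.ensure_dir(self.outdir / "cluster")
            calls = pd.read_csv(self.outdir / "selscan" / "psg_calls.tsv", sep="\t")
            gravy_df = pd.read_csv(self.outdir / "profile" / "gravy.tsv", sep="\t")
            outputs = []
            if not calls.empty:
                calls = calls.rename(columns={"omega2": "omega"})
                table = cluster.build_feature_table(
                    calls[["gene_id", "omega", "percent_sites", "omega_capped"]],
                    dict(zip(gravy_df["gene_id"], gravy_df["delta_gravy"])),
                    omega_cap=self.cfg.omega_cap,
                )
            else:
                table = pd.DataFrame(columns=["gene_id", *cluster.FEATURE_COLUMNS])
            if len(table) >= max(self.cfg.k, 2):
                assigned, _ = cluster.cluster_features(
                    table, k=self.cfg.k, n_init=self.cfg.n_init, seed=self.cfg.seed
                )
            else:
                assigned = table.assign(cluster=0 if len(table) else [])
            assigned.to_csv(out / "clusters.tsv", sep="\t", index=False)
            outputs.append(out / "clusters.tsv")
            term_map = json.loads((self.inputs / "go_terms.json").read_text())
            background = set(
                pd.read_csv(self.outdir / "selscan" / "branch_tests.tsv", sep="\t")["gene_id"]
            )
            cluster1 = set(assigned.loc[assigned.get("cluster", pd.Series(dtype=int)) == 0, "gene_id"])
            if cluster1:
                enr = cluster.enrich_terms(cluster1, background, term_map)
                enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
                outputs.append(out / "enrichment.tsv")
            return outputs

        return deps, run

    def _plan_electro(self):
        deps = [self.inputs / "channels.fasta", self.inputs / "expression_counts.tsv",
                self.inputs / "reads.tsv", self.inputs / "splice_model.json"]
        deps = [d for d in deps if d.exists()]

        def run() -> list[Path]:
            out = io.ensure_dir(self.outdir / "electro")
            channels = io.read_fasta(self.inputs / "channels.fasta")
            hits = [
                dataclasses.asdict(h)
                for sid, seq in channels.items()
                for h in electro.scan_pore_motif(seq, sequence_id=sid)
            ]
            pd.DataFrame(hits, columns=["sequence_id", "motif", "start", "matched"]).to_csv(
                out / "pore_motifs.tsv", sep="\t", index=False
            )
            counts = pd.read_csv(self.inputs / "expression_counts.tsv", sep="\t")
            electro.fpkm_table(counts).to_csv(out / "fpkm.tsv", sep="\t", index=False)
            model = json.loads((self.inputs / "splice_model.json").read_text())
            records = io.read_block_tsv(self.inputs / "reads.tsv")
            contig = model["contig"]
            res = electro.exon_inclusion(
                records,
                annotation.GenomicInterval(contig, *model["exon"]),
                (
                    annotation.GenomicInterval(contig, *model["upstream"]),
                    annotation.GenomicInterval(contig, *model["downstream"]),
                ),
            )
            pd.DataFrame([{
                "exon_start": res.exon.start, "exon_end": res.exon.end,
                "inclusion_reads": res.inclusion_reads,
                "skipping_reads": res.skipping_reads,
                "inclusion_fraction": res.inclusion_fraction,
            }]).to_csv(out / "exon_inclusion.tsv", sep="\t", index=False)
            return [out / "pore_motifs.tsv", out / "fpkm.tsv", out / "exon_inclusion.tsv"]

        return deps, run


def run_pipeline(config: PipelineConfig) -> RunReport:
    return PipelineRunner(config).run()
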