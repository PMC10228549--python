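"""End-to-end orchestration: simulate -> dereplicate -> search -> profile
-> abundance filter -> ordinate -> classify -> etfb, with a run manifest.

One seed governs every stochastic stage; re-running the same configuration
reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import classify as cls
from . import community, etfb as etfb_mod, io, profiling, simulate
from .dereplicate import DerepParams, dereplicate
from .homology import SearchParams, hits_to_frame, search_genome
from .records import quality_frame


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "cemag_out"
    # simulation scale (used when no external inputs are given)
    n_genomes_per_group: int = 3
    contig_length: int = 50_000
    n_contigs: int = 4
    abundance_experiments: int = 4
    samples_per_experiment: int = 4
    clone_divergence: float = 0.005
    # stage parameters
    search: SearchParams = field(default_factory=SearchParams)
    derep: DerepParams = field(default_factory=DerepParams)
    rules: cls.RuleThresholds = field(default_factory=cls.RuleThresholds)
    ml_algorithm: str = "softmax"
    ml_training_per_group: int = 10
    high_abundance_floor: float = 1.0
    nmds_restarts: int = 4
    permanova_permutations: int = 999
    etfb_margin_min: float = 0.10

    @classmethod
    def from_yaml(cls_, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls_()
        for key, value in raw.items():
            if key == "search":
                cfg.search = SearchParams(**value)
            elif key == "derep":
                cfg.derep = DerepParams(**value)
            elif key == "rules":
                cfg.rules = cls.RuleThresholds(**value)
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cfg

    def apply_overrides(self, overrides: list[str]) -> None:
        for item in overrides:
            key, _, value = item.partition("=")
            if not hasattr(self, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(self, key)
            setattr(self, key, type(current)(yaml.safe_load(value)))


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_all(config: PipelineConfig) -> dict:
    """Execute all stages, writing each stage's outputs plus a manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__, "seed": config.seed, "stages": [], "inputs": {},
    }

    def stage(name: str, fn):
        t0 = time.time()
        try:
            info = fn() or {}
        except Exception as exc:
            manifest["stages"].append({"stage": name, "status": "failed", "error": str(exc)})
            io.write_json(manifest, out / "manifest.json")
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        info.update({"stage": name, "status": "ok",
                     "seconds": round(time.time() - t0, 2)})
        manifest["stages"].append(info)

    state: dict = {}

    def do_simulate():
        sim = simulate.SimConfig(
            seed=config.seed,
            n_genomes_per_group=config.n_genomes_per_group,
            contig_length=config.contig_length,
            n_contigs=config.n_contigs,
            abundance_experiments=config.abundance_experiments,
            samples_per_experiment=config.samples_per_experiment,
            clone_divergence=config.clone_divergence,
        )
        catalog, genomes, truths = simulate.simulate_cohort(sim)
        # plant one near-clone so dereplication has work to do
        clone = simulate.simulate_clone(genomes[0], config.clone_divergence,
                                        seed=config.seed + 17)
        genomes = genomes + [clone]
        gdir = out / "genomes"
        gdir.mkdir(exist_ok=True)
        for g in genomes:
            io.write_genome_fasta(g, gdir / f"{g.genome_id}.fasta")
        io.write_catalog(catalog, out / "catalog.faa", out / "catalog.tsv")
        io.write_tsv(quality_frame(genomes), out / "quality.tsv")
        io.write_json([t.to_dict() for t in truths], out / "truth.json")
        state.update(catalog=catalog, genomes=genomes, truths=truths, sim=sim)
        return {"n_genomes": len(genomes)}

    def do_dereplicate():
        quality = quality_frame(state["genomes"])
        clusters = dereplicate(state["genomes"], quality, config.derep)
        io.write_tsv(clusters, out / "derep_clusters.tsv")
        reps = set(clusters[clusters.is_representative == 1].genome_id)
        state["genomes"] = [g for g in state["genomes"] if g.genome_id in reps]
        state["truths"] = [t for t in state["truths"] if t.genome_id in reps]
        return {"n_clusters": int(clusters.is_representative.sum()),
                "n_input": len(clusters)}

    def do_search():
        all_hits = []
        for g in state["genomes"]:
            all_hits.extend(search_genome(state["catalog"], g, config.search))
        io.write_tsv(hits_to_frame(all_hits), out / "hits.tsv")
        state["hits"] = all_hits
        return {"n_hits": len(all_hits)}

    def do_profile():
        profiles = []
        by_genome: dict[str, list] = {}
        for h in state["hits"]:
            by_genome.setdefault(h.genome_id, []).append(h)
        for g in state["genomes"]:
            profiles.append(profiling.build_profile(
                by_genome.get(g.genome_id, []), state["catalog"], g.genome_id))
        matrix = profiling.profile_matrix(profiles, state["catalog"])
        matrix.to_csv(out / "profiles.tsv", sep="\t", lineterminator="\n")
        pathway_cols = state["catalog"].pathway_names
        _, leaves, newick = profiling.hierarchical_cluster(matrix[pathway_cols])
        (out / "dendrogram.nwk").write_text(newick + "\n")
        state["profiles"] = profiles
        state["matrix"] = matrix
        return {"n_profiles": len(profiles)}

    def do_abundance():
        table = simulate.simulate_abundance(state["truths"], state["sim"])
        table.write(out / "abundance.tsv", out / "samples.tsv")
        present, high, summary = community.presence_and_filter(
            table, high_floor=config.high_abundance_floor)
        io.write_tsv(summary, out / "abundance_summary.tsv")
        state["table"] = table
        state["high"] = high
        return {"n_samples": len(table.sample_ids), "n_high_abundance": len(high)}

    def do_ordinate():
        bc = community.bray_curtis_matrix(state["table"])
        res = community.nmds(bc, n_restarts=config.nmds_restarts, seed=config.seed)
        res.coordinates.round(6).to_csv(out / "nmds.tsv", sep="\t",
                                        lineterminator="\n")
        labels = state["table"].experiment_of().values
        stats = community.pairwise_permanova_bh(
            bc, labels, n_perm=config.permanova_permutations, seed=config.seed)
        io.write_tsv(stats.round(6), out / "permanova.tsv")
        io.write_json({"stress": round(res.stress, 6),
                       "n_restarts": res.n_restarts,
                       "converged": bool(res.converged)}, out / "ordination.json")
        return {"stress": round(res.stress, 4)}

    def do_classify():
        rules = [cls.rule_classify(p, config.rules) for p in state["profiles"]]
        # independent synthetic training cohort
        train_sim = simulate.SimConfig(
            seed=config.seed + 9001,
            n_genomes_per_group=config.ml_training_per_group,
            contig_length=config.contig_length,
            n_contigs=config.n_contigs,
        )
        _, tr_genomes, tr_truths = simulate.simulate_cohort(
            train_sim, catalog=state["catalog"])
        tr_profiles = [
            profiling.build_profile(
                search_genome(state["catalog"], g, config.search),
                state["catalog"], g.genome_id)
            for g in tr_genomes
        ]
        tr_matrix = profiling.profile_matrix(tr_profiles, state["catalog"])
        tr_labels = pd.Series({t.genome_id: t.true_group for t in tr_truths}).loc[
            tr_matrix.index]
        model, report = cls.train_classifier(
            tr_matrix, tr_labels, algorithm=config.ml_algorithm, seed=config.seed)
        ml_calls, counts = cls.classify_cohort(
            model, state["matrix"], high_abundance=state["high"] & set(state["matrix"].index))
        venn = cls.compare_methods(
            [r for r in rules if r.genome_id in {c.genome_id for c in ml_calls}],
            ml_calls)
        io.write_tsv(pd.concat([cls.calls_to_frame(rules),
                                cls.calls_to_frame(ml_calls)]), out / "calls.tsv")
        io.write_tsv(counts, out / "group_counts.tsv")
        io.write_json(venn, out / "venn.json")
        io.write_json({
            "cv_logloss": round(report.cv_logloss, 6),
            "baseline_logloss": round(report.baseline_logloss, 6),
            "improvement_percent": round(report.improvement_percent, 4),
            "average_precision": {k: round(v, 6) for k, v in report.average_precision.items()},
            "roc_auc": {k: round(v, 6) for k, v in report.roc_auc.items()},
        }, out / "ml_metrics.json")
        state["rules"] = rules
        state["ml_calls"] = ml_calls
        return {"n_rule_calls": len(rules), "n_ml_calls": len(ml_calls)}

    def do_etfb():
        refs = simulate_etfb_references(state["catalog"], seed=config.seed)
        ref_fasta = {f"{r.ref_id}|{r.label}": r.sequence for r in refs}
        io.write_fasta(ref_fasta, out / "etfb_refs.faa")
        groups = {r.genome_id: r.group for r in state["rules"]}
        all_calls = []
        for g in state["genomes"]:
            all_calls.extend(etfb_mod.call_genome_etfb(
                g, refs, config.search, config.etfb_margin_min))
        io.write_tsv(etfb_mod.calls_to_frame(all_calls), out / "etfb_calls.tsv")
        io.write_tsv(etfb_mod.summarize_etfb(all_calls, groups), out / "etfb_summary.tsv")
        return {"n_etfb_calls": len(all_calls)}

    for name, fn in [
        ("simulate", do_simulate), ("dereplicate", do_dereplicate),
        ("search", do_search), ("profile", do_profile),
        ("abundance", do_abundance), ("ordinate", do_ordinate),
        ("classify", do_classify), ("etfb", do_etfb),
    ]:
        stage(name, fn)

    for f in sorted(out.glob("*.tsv")) + sorted(out.glob("*.json")):
        if f.name != "manifest.json":
            manifest["inputs"][f.name] = _digest(f)
    io.write_json(manifest, out / "manifest.json")
    return manifest


def simulate_etfb_references(catalog, seed: int = 0, n_per_label: int = 3,
                             ref_identity: float = 0.92):
    """Labeled EtfB reference set derived from the catalog's two EtfB
    variants (ecLDH-partnered roster member, ACD-partnered companion),
    mutated to ``ref_identity`` so each label has several distinct
    references."""
    rng = np.random.default_rng(seed + 31)
    lau_base = catalog.get_enzyme("EtfB").sequence
    acd_base = catalog.extras[simulate.ETFB_ACD]
    refs = []
    for label, base in (("LAU_associated", lau_base), ("ACD_associated", acd_base)):
        for i in range(n_per_label):
            seq = base if i == 0 else simulate.mutate_protein(base, ref_identity, rng)
            refs.append(etfb_mod.EtfBReference(f"{label[:3]}_ref{i + 1}", seq, label))
    return refs
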