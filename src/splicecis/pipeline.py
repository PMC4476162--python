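"""End-to-end pipeline orchestration with caching and a run manifest.

A single YAML config drives the stages in dependency order:

    simulate? -> traits -> trends -> constraint -> intragene -> popgen
              -> phylocorr

Each stage records a hash of its configuration and inputs in manifest.json;
re-running with unchanged inputs skips stages whose outputs exist and whose
hash matches ("cached"). Seeds for every stochastic stage derive from the
top-level seed and are recorded, so a manifest suffices to reproduce every
output exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time

import numpy as np
import pandas as pd

log = logging.getLogger("splice-cis")

STAGES = ["simulate", "traits", "trends", "constraint", "intragene",
          "popgen", "phylocorr"]


class ConfigError(Exception):
    pass


class StageError(Exception):
    pass


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _stage_seed(base_seed: int, stage: str) -> int:
    return int.from_bytes(
        hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()[:4],
        "big") % (2 ** 31)


class PipelineRun:
    """Executes the configured stages into an output directory."""

    def __init__(self, config: dict, out_dir: str):
        if not isinstance(config, dict):
            raise ConfigError("config must be a mapping")
        self.config = config
        self.out = out_dir
        self.seed = int(config.get("seed", 0))
        os.makedirs(out_dir, exist_ok=True)
        self.manifest_path = os.path.join(out_dir, "manifest.json")
        self.manifest = {"stages": {}, "seed": self.seed,
                         "config_hash": _hash_obj(config)}
        if os.path.exists(self.manifest_path):
            try:
                with open(self.manifest_path) as fh:
                    self.manifest = json.load(fh)
            except (OSError, json.JSONDecodeError):
                pass
        self._genes = None
        self._genome_path = None
        self._features = None

    # ----------------------------------------------------------------- utils
    def _paths(self):
        sim = self.config.get("simulate")
        inputs = self.config.get("inputs", {})
        base = os.path.join(self.out, "simulated") if sim is not None else None
        return {
            "gff": inputs.get("gff") or (base and os.path.join(
                base, "annotation.gff3")),
            "fasta": inputs.get("fasta") or (base and os.path.join(
                base, "genome.fasta")),
            "orthologs": inputs.get("orthologs") or (base and os.path.join(
                base, "orthologs")),
            "ese": inputs.get("ese") or (base and os.path.join(
                base, "ese_hexamers.txt")),
            "polymorphism": inputs.get("polymorphism") or (base and
                os.path.join(base, "polymorphism")),
            "tree": inputs.get("tree") or (base and os.path.join(
                base, "tree.nwk")),
            "traits": inputs.get("traits"),
        }

    def _stage_fingerprint(self, stage: str, files=()) -> str:
        parts = {"config": self.config.get(stage),
                 "seed": self.seed,
                 "files": {f: _hash_file(f) for f in files
                           if f and os.path.exists(f)}}
        return _hash_obj(parts)

    def _cached(self, stage: str, fingerprint: str, outputs) -> bool:
        rec = self.manifest["stages"].get(stage)
        return (rec is not None and rec.get("fingerprint") == fingerprint
                and all(os.path.exists(o) for o in outputs))

    def _record(self, stage: str, fingerprint: str, outputs, t0: float,
                status: str = "ok", **extra):
        self.manifest["stages"][stage] = {
            "fingerprint": fingerprint, "outputs": list(outputs),
            "status": status, "wall_s": round(time.time() - t0, 2),
            "seed": _stage_seed(self.seed, stage), **extra}
        with open(self.manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)

    def _load_genes(self):
        from .gene_models import (load_and_filter_genes,
                                  extract_internal_exon_features)

        if self._genes is None:
            p = self._paths()
            if not p["gff"] or not os.path.exists(p["gff"]):
                raise StageError(f"missing annotation input {p['gff']!r}")
            genes, rej = load_and_filter_genes(p["gff"], p["fasta"])
            self._genes = genes
            self._rejections = rej
            self._features = {g.gene_id: extract_internal_exon_features(g)
                              for g in genes}
        return self._genes, self._features

    # ---------------------------------------------------------------- stages
    def run(self, only=None):
        for stage in STAGES:
            if stage == "simulate" and self.config.get("simulate") is None:
                continue
            if stage != "simulate" and self.config.get(stage) is None:
                continue
            if only and stage not in only:
                continue
            t0 = time.time()
            try:
                getattr(self, f"stage_{stage}")(t0)
            except (StageError, ValueError, OSError) as err:
                log.error("stage %s failed: %s", stage, err)
                self._record(stage, "", [], t0, status="failed",
                             error=str(err))
                raise StageError(f"stage {stage} failed: {err}") from err
        return self.manifest

    def stage_simulate(self, t0):
        from .synthetic_data import SimulationConfig, write_bundle

        out = os.path.join(self.out, "simulated")
        fp = self._stage_fingerprint("simulate")
        marker = os.path.join(out, "manifest.json")
        if self._cached("simulate", fp, [marker]):
            log.info("simulate: cached")
            return
        cfg_dict = dict(self.config.get("simulate") or {})
        cfg_dict.setdefault("seed", _stage_seed(self.seed, "simulate"))
        cfg = SimulationConfig(**cfg_dict)
        write_bundle(cfg, out)
        self._record("simulate", fp, [marker], t0,
                     n_genes=cfg.n_genes)
        log.info("simulate: wrote %s", out)

    def stage_traits(self, t0):
        from .gene_models import compute_genomic_traits, features_to_table

        p = self._paths()
        fp = self._stage_fingerprint("traits", [p["gff"], p["fasta"]])
        traits_out = os.path.join(self.out, "genomic_traits.tsv")
        feat_out = os.path.join(self.out, "exon_features.tsv")
        if self._cached("traits", fp, [traits_out, feat_out]):
            log.info("traits: cached")
            return
        genes, features = self._load_genes()
        species = self.config.get("traits", {}).get("species", "species")
        tr = compute_genomic_traits(genes, species)
        pd.DataFrame([tr.__dict__]).to_csv(traits_out, sep="\t", index=False)
        flat = [f for fs in features.values() for f in fs]
        features_to_table(flat).to_csv(feat_out, sep="\t", index=False)
        self._record("traits", fp, [traits_out, feat_out], t0,
                     n_genes=len(genes),
                     n_rejected=len(self._rejections))
        log.info("traits: %d genes (%d rejected), %d internal exons",
                 len(genes), len(self._rejections), len(flat))

    def stage_trends(self, t0):
        from .junction_trends import (cis_motif_usage_metric,
                                      exon_codon_records, splice_site_usage)

        cfg = self.config.get("trends", {})
        out = os.path.join(self.out, "cis_motif_usage.tsv")
        p = self._paths()
        fp = self._stage_fingerprint("trends", [p["gff"]])
        if self._cached("trends", fp, [out]):
            log.info("trends: cached")
            return
        genes, features = self._load_genes()
        pool = [ec for g in genes for ec in exon_codon_records(g)]
        usage = cis_motif_usage_metric(
            pool, subsample_size=int(cfg.get("subsample", 5000)),
            repetitions=int(cfg.get("reps", 100)),
            seed=_stage_seed(self.seed, "trends"),
            both_ends=bool(cfg.get("both_ends", False)),
            species=cfg.get("species", "species"))
        flat = [f for fs in features.values() for f in fs]
        sites = splice_site_usage(flat, species=cfg.get("species", "species"))
        row = {**usage.__dict__, "P1": sites.P1, "P2": sites.P2}
        pd.DataFrame([row]).to_csv(out, sep="\t", index=False)
        self._record("trends", fp, [out], t0)
        log.info("trends: Y_codon=%.4f P1=%.3f", usage.Y_codon, sites.P1)

    def _aligned_features(self, motifs):
        from Bio import SeqIO
        from .ese_constraint import align_gene_features

        p = self._paths()
        genes, features = self._load_genes()
        afs = []
        for g in genes:
            path = os.path.join(p["orthologs"], f"{g.gene_id}.fasta")
            if not os.path.exists(path):
                continue
            recs = list(SeqIO.parse(path, "fasta"))
            if len(recs) != 2:
                raise StageError(f"ortholog file {path} must hold 2 records")
            afs += align_gene_features(g, features[g.gene_id],
                                       str(recs[0].seq).upper(),
                                       str(recs[1].seq).upper())
        if not afs:
            raise StageError("no ortholog alignments found")
        return genes, afs

    def stage_constraint(self, t0):
        from .ese_constraint import (binned_flank_constraint,
                                     gene_level_constraint, load_hexamer_set,
                                     selection_proportion_per_exon)

        cfg = self.config.get("constraint", {})
        p = self._paths()
        fp = self._stage_fingerprint("constraint", [p["ese"]])
        outs = [os.path.join(self.out, f)
                for f in ("constraint_bins_5prime.tsv",
                          "constraint_bins_3prime.tsv",
                          "constraint_per_exon.tsv",
                          "constraint_per_gene.tsv",
                          "constraint_report.json")]
        if self._cached("constraint", fp, outs):
            log.info("constraint: cached")
            return
        motifs = load_hexamer_set(p["ese"], "ese")
        genes, afs = self._aligned_features(motifs)
        seed = _stage_seed(self.seed, "constraint")
        bins = binned_flank_constraint(
            afs, motifs, n_bins=int(cfg.get("bins", 20)),
            pseudo_reps=int(cfg.get("pseudo_reps", 100)), seed=seed)
        bins["5prime"].to_csv(outs[0], sep="\t", index=False)
        bins["3prime"].to_csv(outs[1], sep="\t", index=False)
        sel = selection_proportion_per_exon(afs, motifs)
        pd.concat([sel[e]["table"].assign(end=e) for e in sel]).to_csv(
            outs[2], sep="\t", index=False)
        gl = gene_level_constraint(
            genes, afs, motifs, cutoff=int(cfg.get("cutoff", 102)),
            resample_reps=int(cfg.get("resample_reps", 1000)),
            perm_m=int(cfg.get("perm_m", 1000)), seed=seed)
        gl["table"].to_csv(outs[3], sep="\t", index=False)
        report = {
            "selection_vs_log_intron": {
                e: {k: sel[e][k] for k in ("slope", "intercept", "rho", "p")}
                for e in sel},
            "gene_level_correlations": gl["correlations"],
            "resampling_significant_fraction":
                gl["resampling_significant_fraction"],
            "mean_bin_constraint": {
                e: float(np.nanmean(bins[e]["constraint"])) for e in bins},
        }
        with open(outs[4], "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        self._record("constraint", fp, outs, t0)
        log.info("constraint: mean bin constraint 5'=%.3f",
                 report["mean_bin_constraint"]["5prime"])

    def stage_intragene(self, t0):
        from .ese_constraint import load_hexamer_set
        from .intragene_tests import (loess_residual_test,
                                      paired_density_records,
                                      second_vs_penultimate_test,
                                      splice_site_intron_size_test)

        cfg = self.config.get("intragene", {})
        p = self._paths()
        fp = self._stage_fingerprint("intragene", [p["ese"]])
        out = os.path.join(self.out, "intragene_report.json")
        rec_out = os.path.join(self.out, "paired_density_records.tsv")
        if self._cached("intragene", fp, [out, rec_out]):
            log.info("intragene: cached")
            return
        motifs = load_hexamer_set(p["ese"], "ese")
        genes, features = self._load_genes()
        recs = paired_density_records(genes, motifs)
        pd.DataFrame([r.__dict__ for r in recs]).to_csv(rec_out, sep="\t",
                                                        index=False)
        report = {"n_records": len(recs)}
        if recs:
            report["second_vs_penultimate"] = second_vs_penultimate_test(recs)
            if len(recs) >= 30:
                report["loess_residuals"] = loess_residual_test(
                    recs, span=float(cfg.get("span", 0.75)))
        flat = [f for fs in features.values() for f in fs]
        try:
            report["aggt_intron_size"] = splice_site_intron_size_test(flat)
        except ValueError as err:
            report["aggt_intron_size"] = {"error": str(err)}
        with open(out, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        self._record("intragene", fp, [out, rec_out], t0)
        log.info("intragene: %d paired records", len(recs))

    def stage_popgen(self, t0):
        from .popgen_theta import combined_estimates, load_polymorphism_fasta

        cfg = self.config.get("popgen", {})
        p = self._paths()
        out = os.path.join(self.out, "ne_mu.tsv")
        fp = self._stage_fingerprint("popgen")
        if self._cached("popgen", fp, [out]):
            log.info("popgen: cached")
            return
        pdir = p["polymorphism"]
        if not pdir or not os.path.isdir(pdir):
            raise StageError(f"missing polymorphism directory {pdir!r}")
        samples = [load_polymorphism_fasta(
            os.path.join(pdir, f),
            species=cfg.get("species", "species"),
            locus_class=cfg.get("mode", "intron"))
            for f in sorted(os.listdir(pdir)) if f.endswith(".fasta")]
        if not samples:
            raise StageError("no polymorphism FASTA files")
        est = combined_estimates(samples,
                                 ploidy_factor=float(cfg.get("ploidy", 4)))
        pd.DataFrame([est.__dict__]).to_csv(out, sep="\t", index=False)
        self._record("popgen", fp, [out], t0)
        log.info("popgen: theta_pi=%.5f", est.theta_pi)

    def stage_phylocorr(self, t0):
        from .phylo_comparative import (bm_correlation_evidence, load_tree,
                                        trait_table_on_tree)

        cfg = self.config.get("phylocorr", {})
        p = self._paths()
        out = os.path.join(self.out, "phylo_correlations.json")
        fp = self._stage_fingerprint("phylocorr",
                                     [p["tree"], p["traits"] or ""])
        if self._cached("phylocorr", fp, [out]):
            log.info("phylocorr: cached")
            return
        traits_path = p["traits"] or os.path.join(
            self.out, "simulated", "traits.tsv")
        if not os.path.exists(traits_path):
            raise StageError(f"missing trait table {traits_path!r}")
        tree = load_tree(p["tree"])
        table = pd.read_csv(traits_path, sep="\t", index_col=0)
        tree, table = trait_table_on_tree(tree, table)
        pairs = cfg.get("pairs") or [list(table.columns[:2])]
        mode = cfg.get("mode", "ml")
        results = {}
        for x, y in pairs:
            ev = bm_correlation_evidence(
                tree, table[x].to_dict(), table[y].to_dict(), mode=mode,
                seed=_stage_seed(self.seed, f"phylocorr:{x}:{y}"))
            results[f"{y}~{x}"] = {
                "statistic": ev.statistic if np.isfinite(ev.statistic)
                else "inf",
                "rho_hat": ev.rho_hat, "evidence_class": ev.evidence_class,
                "mode": ev.mode, "k": ev.k}
        with open(out, "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True)
        self._record("phylocorr", fp, [out], t0)
        log.info("phylocorr: %d pairs", len(results))


def run_pipeline(config: dict, out_dir: str) -> dict:
    """Run all configured stages; returns the manifest."""
    return PipelineRun(config, out_dir).run()
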