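"""End-to-end pipeline: simulate -> GL -> heterozygosity -> ROH -> mtDNA -> structure.

``run_pipeline`` executes the configured stages against a synthetic
two-epoch dataset, writes every intermediate in its standard text format,
and emits a JSON report plus a run manifest with full seed provenance.
Rerunning with the same config and seed reproduces every output
bit-identically.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

from . import __version__, gl, hetcal, io, mthap, rohscan, simdata, structure


class PipelineError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


_SIM_FIELDS = {f.name for f in dataclasses.fields(simdata.SimConfig)}


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run every stage as configured and return the combined report.

    ``config`` holds SimConfig fields at top level (or under ``simulate``)
    plus optional ``analysis`` settings (filters, ROH parameters, admixture
    K and number of starts, mitochondrial scenario).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_keys = {k: v for k, v in {**config, **config.get("simulate", {})}.items()
                if k in _SIM_FIELDS}
    analysis = config.get("analysis", {})
    for key in ("input_vcf", "input_fasta"):
        if key in config and not Path(config[key]).exists():
            raise FileNotFoundError(f"configured {key} does not exist: {config[key]}")

    cfg = simdata.SimConfig(**sim_keys)
    seeds = {"simulate": cfg.seed}
    report: dict = {"version": __version__, "seed": cfg.seed}
    manifest = io.RunManifest(
        command="run", config=config, seeds=seeds, started=io.utc_now()
    )

    # --- simulate -----------------------------------------------------------
    stage = "simulate"
    try:
        geno, truth = simdata.simulate_genotypes(cfg)
        froh_target = analysis.get("froh_target", 0.0)
        if froh_target:
            seeds["plant_roh"] = cfg.seed + 1
            geno, truth = simdata.plant_roh(
                geno, truth, froh_target, seed=seeds["plant_roh"]
            )
        is_hist = np.array(geno.epochs) == "historic"
        cov = np.where(is_hist, cfg.coverage_historic, cfg.coverage_contemporary)
        damage = np.where(is_hist, cfg.damage_rate, 0.0)  # aDNA damage: museum only
        seeds["simulate_reads"] = cfg.seed + 2
        pile = simdata.simulate_reads(
            geno, cov, cfg.error_rate, damage, seed=seeds["simulate_reads"]
        )
        io.write_vcf(geno, outdir / "genotypes.vcf", seed=cfg.seed)
        io.write_fai(geno.scaffold_lengths, outdir / "scaffolds.fai")
        io.write_truth_table(truth, outdir / "truth.tsv")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- genotype likelihoods ----------------------------------------------
    stage = "gl"
    try:
        error_model = gl.ErrorModel(rate=cfg.error_rate)
        gls = gl.call_genotype_likelihoods(pile, error_model)
        gls.maf = gl.estimate_maf_em(gls)
        filtered = gl.filter_sites(
            gls,
            min_maf=analysis.get("min_maf", 0.05),
            snp_p=analysis.get("snp_pval", 1e-6),
            min_ind=analysis.get("min_ind", max(1, geno.n_individuals // 2)),
            rm_transitions=analysis.get("rm_transitions", True),
        )
        io.write_beagle_gl(filtered, outdir / "genolike.beagle")
        report["n_sites_filtered"] = filtered.n_sites
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- heterozygosity + calibration ---------------------------------------
    stage = "het"
    try:
        cov_mean = pile.depth.mean(axis=1)
        # heterozygosity from transversion sites only: damage-driven C/T and
        # G/A false heterozygotes would otherwise dominate historic samples
        trans = np.array(
            [gl.is_transition(a, b) for a, b in zip(gls.major, gls.minor)]
        )
        windows = hetcal.windowed_heterozygosity(
            gls.subset_sites(~trans), coverage=cov_mean
        )
        per_ind = hetcal.genomewide_heterozygosity(windows)
        seeds["calibrate"] = cfg.seed + 3
        ref_ind = int(np.argmax(cov_mean))
        curve = hetcal.build_calibration_curve(
            pile, cfg.error_rate, degree=analysis.get("calibration_degree", 3),
            seed=seeds["calibrate"], individual=ref_ind,
        )
        corrected = {}
        for i, sample in enumerate(geno.samples):
            if sample not in per_ind.index:
                continue
            raw = float(per_ind[sample])
            try:
                corrected[sample] = float(
                    hetcal.apply_correction(raw, float(cov_mean[i]), curve)
                )
            except ValueError:
                corrected[sample] = float("nan")
        het_df = per_ind.rename("raw_het").to_frame()
        het_df["coverage"] = [
            float(cov_mean[geno.samples.index(s)]) for s in het_df.index
        ]
        het_df["corrected_het"] = [corrected.get(s, float("nan")) for s in het_df.index]
        het_df.to_csv(outdir / "heterozygosity.tsv", sep="\t")
        by_epoch = {
            e: float(np.mean([per_ind[s] for s, ep in zip(geno.samples, geno.epochs)
                              if ep == e and s in per_ind.index]))
            for e in sorted(set(geno.epochs))
        }
        report["mean_raw_het_by_epoch"] = by_epoch
        groups = [
            [per_ind[s] for s, ep in zip(geno.samples, geno.epochs)
             if ep == e and s in per_ind.index]
            for e in sorted(set(geno.epochs))
        ]
        h, p = hetcal.kruskal_wallis(groups)
        report["kruskal_wallis"] = {"H": h, "p": p}
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- runs of homozygosity ----------------------------------------------
    stage = "roh"
    try:
        params = rohscan.ROHParams(**analysis.get("roh_params", {}))
        min_scaf = analysis.get("froh_min_scaffold_bp", 10_000_000)
        # scan hard genotype calls at the filtered SNP panel (monomorphic
        # sites carry no ROH information and would saturate the scan)
        calls = gl.call_genotypes(filtered)
        profiles = []
        for i, sample in enumerate(geno.samples):
            segs = rohscan.call_roh(
                filtered.scaffolds, filtered.positions, calls[i], params
            )
            profiles.append(
                rohscan.compute_froh(
                    segs, geno.scaffold_lengths, min_scaffold_bp=min_scaf,
                    individual=sample,
                )
            )
        io.roh_table(profiles).to_csv(outdir / "roh_segments.tsv", sep="\t", index=False)
        io.froh_table(profiles).to_csv(outdir / "froh.tsv", sep="\t", index=False)
        report["mean_froh_by_epoch"] = {
            e: float(np.mean([p.froh for p, ep in zip(profiles, geno.epochs) if ep == e]))
            for e in sorted(set(geno.epochs))
        }
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- mitochondrial haplotypes -------------------------------------------
    stage = "hapdiv"
    try:
        mt_cfg = analysis.get("mt", {})
        seeds["simulate_mt"] = cfg.seed + 4
        mt = simdata.simulate_mt_haplotypes(
            n_historic=cfg.n_historic,
            n_contemporary=cfg.n_contemporary,
            n_haplotypes=mt_cfg.get("n_haplotypes", 5),
            seq_length=mt_cfg.get("seq_length", 1000),
            seed=seeds["simulate_mt"],
            historic_freqs=mt_cfg.get("historic_freqs"),
            drop_rare=mt_cfg.get("drop_rare", 2),
        )
        io.write_mt_fasta(mt.records, outdir / "mt.fasta", seed=seeds["simulate_mt"])
        table = mthap.call_haplotypes(mt.records)
        hist = table.subgroup(epoch="historic")
        cont = table.subgroup(epoch="contemporary")
        seeds["permutation"] = cfg.seed + 5
        perm = mthap.permutation_test_hd(
            hist, cont, n_permutations=mt_cfg.get("n_permutations", 10_000),
            seed=seeds["permutation"],
        )
        report["hd"] = {
            "historic": mthap.haplotype_diversity(hist),
            "contemporary": mthap.haplotype_diversity(cont),
            "delta": perm.observed,
            "permutation_p": perm.p_value,
        }
        net = mthap.median_joining_network(table)
        import networkx as nx

        nx.write_gml(net, str(outdir / "mt_network.gml"))
        mthap.network_edge_table(net).to_csv(
            outdir / "mt_network_edges.tsv", sep="\t", index=False
        )
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- structure -----------------------------------------------------------
    stage = "structure"
    try:
        cov_mat = structure.gl_covariance(filtered)
        vals, vecs, scores = structure.pca(cov_mat)
        np.savetxt(outdir / "covariance.tsv", cov_mat.matrix, delimiter="\t")
        import pandas as pd

        pd.DataFrame(
            scores[:, :4], index=filtered.samples,
            columns=[f"PC{k + 1}" for k in range(min(4, scores.shape[1]))],
        ).to_csv(outdir / "pc_scores.tsv", sep="\t")
        seeds["admixture"] = cfg.seed + 6
        fit = structure.admixture_em(
            filtered, K=analysis.get("admixture_K", 2),
            seed=seeds["admixture"], n_starts=analysis.get("admixture_starts", 5),
        )
        pd.DataFrame(
            fit.Q, index=filtered.samples,
            columns=[f"Q{k + 1}" for k in range(fit.K)],
        ).to_csv(outdir / "admixture_Q.tsv", sep="\t")
        report["admixture_loglik"] = fit.loglik
        report["pc1_variance_fraction"] = float(
            np.maximum(vals, 0)[0] / np.maximum(vals, 0).sum()
        )
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    manifest.seeds = seeds
    manifest.finished = io.utc_now()
    manifest.input_checksums = {
        p.name: io.file_checksum(p)
        for p in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.vcf"))
    }
    manifest.save(outdir / "manifest.json")
    import json

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
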