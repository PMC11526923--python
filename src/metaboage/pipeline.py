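"""End-to-end orchestration: simulate/load -> normalize -> kinship -> PCA ->
association -> covariation -> contrasts -> mediation, with a deterministic
manifest.

Every intermediate is plain delimited text.  The manifest records the config
snapshot, seeds, per-stage row/column counts and sha256 checksums of the
result tables; stage timings go to the log, not the manifest, so fixed-seed
runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, covariation, io, kinship, lmm, mediation, multivariate, preprocess
from .simulate import (
    DIET_LEVELS,
    SimulationConfig,
    default_mediator_spec,
    simulate_genotypes,
    simulate_phenotypes,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds for a run in one namespace; nothing is hard-coded in stages."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    max_missing: float = 0.10
    max_hemolysis_grade: int = 3
    knn_k: int = 10
    min_maf: float = 0.01
    min_callrate: float = 0.95
    fdr_alpha: float = 0.05
    tw_alpha: float = 0.05
    purebred_threshold: float = 0.85
    purebred_min_dogs: int = 8
    mediator: str = "creatinine"
    n_boot: int = 2000
    rho_threshold: float = 0.3
    max_pcs_heritability: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        sim = d["simulation"]
        for key in ("effect_table", "h2_table"):
            if sim.get(key) is not None:
                sim[key] = "<explicit table>"
        sim["mediator_spec"] = {
            "a": self.simulation.mediator_spec.a,
            "sigma_m": self.simulation.mediator_spec.sigma_m,
            "targets": {str(k): list(v) for k, v in self.simulation.mediator_spec.targets.items()},
        }
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class Stage:
    """Context helper: logs timing and records counts into the manifest."""

    def __init__(self, manifest: dict, name: str):
        self.manifest = manifest
        self.name = name

    def __enter__(self):
        self.t0 = time.monotonic()
        log.info("stage %s: start", self.name)
        self.entry: dict = {}
        self.manifest["stages"][self.name] = self.entry
        return self.entry

    def __exit__(self, exc_type, exc, tb):
        dt = time.monotonic() - self.t0
        log.info("stage %s: %s in %.2fs", self.name, "FAILED" if exc else "done", dt)
        if exc:
            self.entry["failed"] = repr(exc)
        return False


def run_all(
    config: PipelineConfig,
    outdir: str | Path,
    synthetic: bool = True,
    inputs: dict[str, str] | None = None,
) -> dict:
    """Execute the full analysis; returns the manifest (also written as JSON).

    With ``synthetic`` the cohort is generated from ``config.simulation``
    (seeded by ``config.seed``); otherwise ``inputs`` must name
    ``metabolites``, ``sample_meta``, ``cohort`` and either ``genotypes`` or
    ``grm`` files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.snapshot(),
        "stages": {},
        "outputs": {},
    }

    # --- inputs ------------------------------------------------------------
    with Stage(manifest, "inputs") as st:
        if synthetic:
            sim = config.simulation
            if sim.seed != config.seed:
                sim = dataclasses.replace(sim, seed=config.seed)
            if not sim.mediator_spec.targets:
                sim = dataclasses.replace(
                    sim,
                    mediator_spec=default_mediator_spec(
                        sim, np.random.default_rng((config.seed, 0xC))
                    ),
                )
            genotypes, ancestry = simulate_genotypes(sim)
            kin_all = kinship.compute_grm(
                kinship.filter_snps(genotypes, config.min_maf, config.min_callrate)
            )
            matrix, cohort, truth = simulate_phenotypes(sim, genotypes, kin_all)
            io.write_matrix(truth.true_beta, outdir / "true_beta.tsv")
            st["n_dogs"] = sim.n_dogs
            st["n_metabolites"] = sim.n_metabolites
            st["n_snps"] = sim.n_snps
        else:
            if not inputs:
                raise ValueError("inputs required when synthetic=False")
            values = io.read_matrix(inputs["metabolites"])
            meta = io.read_matrix(inputs["sample_meta"])
            bad = values.index.symmetric_difference(meta.index)
            if len(bad):
                raise ValueError(f"metabolite/sample-meta id mismatch: {list(bad)[:5]}")
            matrix = preprocess.MetaboliteMatrix(values, meta, state="raw")
            cohort = io.read_matrix(inputs["cohort"])
            bad = values.index.symmetric_difference(cohort.index)
            if len(bad):
                raise ValueError(f"metabolite/cohort id mismatch: {list(bad)[:5]}")
            if "grm" in inputs:
                kin_all = kinship.KinshipMatrix.from_rel(inputs["grm"])
            else:
                genotypes = io.read_matrix(inputs["genotypes"])
                kin_all = kinship.compute_grm(
                    kinship.filter_snps(genotypes, config.min_maf, config.min_callrate)
                )
            ancestry = None
            for c in ("checksums",):
                st[c] = {k: _sha256(Path(v)) for k, v in inputs.items()}
            st["n_dogs"] = len(cohort)
            st["n_metabolites"] = matrix.n_metabolites
        kin_all.to_rel(outdir / "grm.rel")
        st["grm_markers"] = kin_all.n_markers

    # --- preprocess --------------------------------------------------------
    with Stage(manifest, "preprocess") as st:
        norm, reports = preprocess.normalize(
            matrix,
            max_missing=config.max_missing,
            max_hemolysis_grade=config.max_hemolysis_grade,
            knn_k=config.knn_k,
        )
        st["dropped_metabolites"] = int(len(reports["dropped_metabolites"]))
        st["dropped_samples"] = int(len(reports["dropped_samples"]))
        st["n_samples"] = norm.n_samples
        st["n_metabolites"] = norm.n_metabolites
        io.write_matrix(norm.values, outdir / "normalized.tsv")
        kin = kin_all.subset(list(norm.values.index))
        cohort = cohort.loc[norm.values.index]

    # --- multivariate ------------------------------------------------------
    with Stage(manifest, "multivariate") as st:
        dec = multivariate.pca(norm)
        dec.tw_p, dec.n_significant = multivariate.tracy_widom_select(
            dec.eigenvalues, n_samples=norm.n_samples, alpha=config.tw_alpha
        )
        st["n_significant_pcs"] = int(dec.n_significant)
        st["var_explained_significant"] = float(
            dec.var_explained[: dec.n_significant].sum()
        )
        io.write_matrix(dec.scores, outdir / "pca_scores.tsv")
        io.write_matrix(dec.loadings, outdir / "pca_loadings.tsv")
        covs = ["age", "weight", "sex", "sterilized", "fasting", "life_stage"]
        if ancestry is not None:
            breed = kinship.classify_purebred(
                kinship.AncestryTable(ancestry.loc[cohort.index]),
                threshold=config.purebred_threshold,
                min_dogs=config.purebred_min_dogs,
            )
            cohort = cohort.assign(breed=breed.astype(str))
            covs.append("breed")
        n_keep = max(dec.n_significant, 1)
        part = multivariate.ancova_partition(
            dec.scores.iloc[:, :n_keep], cohort, covs
        )
        part.table.to_csv(outdir / "variance_partition.tsv", sep="\t", index=False)
        n_h2 = min(n_keep, config.max_pcs_heritability)
        pc_h2 = multivariate.pc_heritability(
            dec.scores.iloc[:, :n_h2], cohort, kin
        )
        pc_h2.to_csv(outdir / "pc_heritability.tsv", sep="\t")
        st["mean_pc_h_snp"] = float(pc_h2["h_snp"].mean())

    # --- association -------------------------------------------------------
    with Stage(manifest, "mwas") as st:
        assoc = lmm.mwas(norm, cohort, kin, alpha=config.fdr_alpha)
        assoc.table.to_csv(outdir / "mwas.tsv", sep="\t", index=False)
        age_hits = assoc.significant("sqrt_age")
        st["interaction_kept"] = assoc.interaction_kept
        st["age_hits"] = len(age_hits)
        st["n_fit"] = len(assoc.fits)

    # --- covariation -------------------------------------------------------
    with Stage(manifest, "covariation") as st:
        adj = covariation.adjust(norm, assoc)
        extra = cohort[["creatinine", "bun"]] if "creatinine" in cohort else None
        corr = covariation.correlate_fdr(adj, alpha=config.fdr_alpha, extra_columns=extra)
        io.write_matrix(corr.r, outdir / "residual_correlation.tsv")
        if corr.tree is not None:
            (outdir / "dendrogram.nwk").write_text(corr.tree.newick() + "\n")
        st["significant_pairs"] = int(len(corr.significant_pairs(config.fdr_alpha)))

    # --- diet contrast and kibble subset -----------------------------------
    with Stage(manifest, "contrasts") as st:
        if "diet" in cohort.columns and cohort["diet"].nunique() > 1:
            diet_assoc = lmm.contrast_covariate(
                norm, cohort, kin, "diet", reference=DIET_LEVELS[0], alpha=config.fdr_alpha
            )
            diet_cols = [
                c for c in diet_assoc.design.X.columns if c.startswith("diet[")
            ]
            diet_assoc.table[
                diet_assoc.table["coefficient"].isin(diet_cols)
            ].to_csv(outdir / "diet_contrasts.tsv", sep="\t", index=False)
            st["diet_hits"] = int(
                sum(len(diet_assoc.significant(c)) for c in diet_cols)
            )
            kibble = cohort["diet"] == DIET_LEVELS[0]
            if kibble.sum() >= 50:
                sub = lmm.subset_refit(norm, cohort, kin, kibble, alpha=config.fdr_alpha)
                sub.table.to_csv(outdir / "kibble_subset_mwas.tsv", sep="\t", index=False)
                st["kibble_dogs"] = int(kibble.sum())
                st["kibble_age_hits"] = len(sub.significant("sqrt_age"))

    # --- mediation ---------------------------------------------------------
    with Stage(manifest, "mediation") as st:
        if config.mediator in cohort.columns and age_hits:
            med = mediation.mediate_panel(
                norm,
                cohort,
                mediator_col=config.mediator,
                metabolites=age_hits,
                alpha=config.fdr_alpha,
                n_boot=config.n_boot,
                seed=config.seed,
                rho_threshold=config.rho_threshold,
            )
            med.to_csv(outdir / "mediation.tsv", sep="\t")
            st["mediated"] = int((med["q"] <= config.fdr_alpha).sum())
            st["n_tested"] = int(len(med))

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(outdir.glob("*.tsv"))
    }
    io.write_json(manifest, outdir / "manifest.json")
    return manifest


def make_report(outdir: str | Path) -> list[Path]:
    """Figures from a completed run directory; missing stages are skipped.

    Each figure's underlying numbers are already on disk as TSV, so the
    images are presentation only.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    written: list[Path] = []

    def save(fig, name: str) -> None:
        p = outdir / name
        fig.savefig(p, dpi=120, metadata={"Date": None})
        plt.close(fig)
        written.append(p)

    mwas_path = outdir / "mwas.tsv"
    if mwas_path.exists():
        t = pd.read_csv(mwas_path, sep="\t")
        age = t[t["coefficient"] == "sqrt_age"]
        fig, ax = plt.subplots(figsize=(6, 4))
        with np.errstate(divide="ignore"):
            ax.scatter(age["beta"], -np.log10(age["p"]), s=8, c=(age["q"] <= 0.05).map({True: "crimson", False: "grey"}))
        thr = age.loc[age["q"] <= 0.05, "p"].max()
        if np.isfinite(thr) and thr > 0:
            ax.axhline(-np.log10(thr), color="red", lw=0.8, ls="--")
        ax.set_xlabel("age effect (beta)")
        ax.set_ylabel("-log10 p")
        save(fig, "fig_age_volcano.png")

    part_path = outdir / "variance_partition.tsv"
    if part_path.exists():
        t = pd.read_csv(part_path, sep="\t")
        wide = t[t["term"] != "residual"].pivot(index="pc", columns="term", values="fraction")
        fig, ax = plt.subplots(figsize=(7, 4))
        wide.plot.bar(stacked=True, ax=ax, width=0.85)
        ax.set_ylabel("fraction of PC variance")
        ax.legend(fontsize=6)
        save(fig, "fig_variance_partition.png")

    h2_path = outdir / "pc_heritability.tsv"
    if h2_path.exists():
        t = pd.read_csv(h2_path, sep="\t")
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.bar(t["pc"], t["h_snp"], color="steelblue")
        ax.set_ylabel("H_SNP")
        save(fig, "fig_pc_heritability.png")

    corr_path = outdir / "residual_correlation.tsv"
    if corr_path.exists():
        r = io.read_matrix(corr_path)
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(r.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
        fig.colorbar(im, ax=ax, shrink=0.8)
        ax.set_title("residual correlation")
        save(fig, "fig_correlation_heatmap.png")

    med_path = outdir / "mediation.tsv"
    if med_path.exists():
        t = pd.read_csv(med_path, sep="\t", index_col=0)
        fig, ax = plt.subplots(figsize=(6, 3.5))
        colors = (t["q"] <= 0.05).map({True: "seagreen", False: "lightgrey"})
        ax.bar(t.index, t["prop_mediated"], color=colors)
        ax.errorbar(
            np.arange(len(t)),
            t["prop_mediated"],
            yerr=np.abs(
                t["prop_mediated"].to_numpy()[None, :]
                - np.vstack([t["ci_lo"] / t["total"], t["ci_hi"] / t["total"]])
            )[::1],
            fmt="none",
            ecolor="black",
            lw=0.7,
        )
        ax.set_ylabel("proportion mediated")
        ax.tick_params(axis="x", rotation=90, labelsize=6)
        save(fig, "fig_proportion_mediated.png")

    return written
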