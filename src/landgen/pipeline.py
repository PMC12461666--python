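"""Config-driven orchestration of the full analysis.

Stages: simulate (or load) -> filter -> structure -> select-env -> gea ->
offset -> donor. Every stage reads and writes declared files under the
output directory, so stages can be re-run individually; a JSON manifest
records seeds, parameters and the counts at each filter step. Identical
config + seed yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, gea, genio, offset, ordination, popstruct, synthdata

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "Pipeline", "run"]


@dataclass
class PipelineConfig:
    """All knobs of one end-to-end run; round-trips through YAML."""

    outdir: str = "landgen_run"
    seed: int = 0
    # input paths (used when simulate = False)
    simulate: bool = True
    genotype_path: str | None = None
    genotype_format: str = "tsv012"
    sites_path: str | None = None
    raster_dir: str | None = None
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    # filtering
    maf_min: float = 0.05
    one_per_contig: bool = True
    # structure
    K_range: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5, 6])
    mask_fraction: float = 0.1
    n_restarts: int = 2
    cv_locus_cap: int = 3000  # loci used in the choose_K CV scan
    n_perm: int = 199
    # environment selection
    alpha_forward: float = 0.01
    n_perm_forward: int = 199
    varclus_cut: float = 0.7
    # GEA
    alpha_gea: float = 0.05
    n_pcs: int = 2
    k_axes: int = 2
    candidate_mode: str = "consensus"  # consensus | union | all
    # offsets
    axes: list[int] = field(default_factory=lambda: [0, 1])
    weighting: str = "sqrt_eigenvalue"
    zprime_threshold: float = 1.0
    max_reference_pairs: int = 2_000_000

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def sim_config(self) -> synthdata.SimConfig:
        kw = dict(self.sim)
        kw.setdefault("seed", self.seed)
        for key in ("grid_shape", "n_zones", "driver_vars"):
            if key in kw and isinstance(kw[key], list):
                kw[key] = tuple(kw[key])
        return synthdata.SimConfig(**kw)


class Pipeline:
    """Stage runner; every stage leaves its artifacts under ``outdir``."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "landgen_version": __version__,
            "seed": config.seed,
            "stages": {},
        }
        self._rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 9000])
        )

    # -- helpers ----------------------------------------------------------

    def _seed(self) -> int:
        return int(self._rng.integers(2**31 - 1))

    def _record(self, stage: str, **info) -> None:
        self.manifest["stages"][stage] = info
        with open(self.outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def _timed(self, stage, fn):
        t0 = time.perf_counter()
        out = fn()
        logger.info("stage %s finished in %.1f s", stage,
                    time.perf_counter() - t0)
        return out

    # -- stages -----------------------------------------------------------

    def stage_simulate(self):
        cfg = self.config
        if cfg.simulate:
            sim = cfg.sim_config()
            g, sites, env, truth = synthdata.simulate(sim)
            genio.write_genotypes(g, self.outdir / "genotypes.tsv")
            genio.write_sites(sites, self.outdir / "sites.csv")
            for var in env.variables:
                for period in env.PERIODS:
                    genio.write_raster(
                        self.outdir / f"env_{var}_{period}.asc",
                        env.grids[var][period],
                        env.xllcorner, env.yllcorner, env.cellsize,
                    )
            truth.locus_effects.to_csv(
                self.outdir / "truth_adaptive_loci.csv", index=False
            )
            pd.DataFrame(
                truth.true_Q,
                index=sites.data["individual_id"],
                columns=[f"q{k}" for k in range(truth.true_Q.shape[1])],
            ).to_csv(self.outdir / "truth_Q.csv")
            self._record(
                "simulate",
                n_individuals=g.n_individuals,
                n_loci=g.n_loci,
                n_sites=int(sites.data["site_id"].nunique()),
                missing_fraction=round(g.missing_fraction(), 4),
                sim_seed=sim.seed,
            )
            self._g, self._sites, self._env, self._truth = g, sites, env, truth
        else:
            g = genio.read_genotypes(cfg.genotype_path, cfg.genotype_format)
            sites = genio.read_sites(cfg.sites_path)
            sites.check_matches(g)
            env = _load_env_dir(Path(cfg.raster_dir), sites)
            self._record("simulate", loaded=True, n_individuals=g.n_individuals,
                         n_loci=g.n_loci)
            self._g, self._sites, self._env, self._truth = g, sites, env, None
        return self._g

    def stage_filter(self):
        cfg = self.config
        g = genio.filter_loci(self._g, cfg.maf_min, cfg.one_per_contig)
        if g.n_loci == 0:
            raise RuntimeError("stage filter: no loci survived filtering")
        genio.write_genotypes(g, self.outdir / "genotypes_filtered.tsv")
        self._record("filter", n_in=self._g.n_loci, n_out=g.n_loci,
                     maf_min=cfg.maf_min)
        self._gf = g
        return g

    def stage_structure(self):
        cfg = self.config
        g, sites = self._gf, self._sites
        g_cv = g
        if g.n_loci > cfg.cv_locus_cap:
            # the CV ranking of K stabilizes well below the full panel size;
            # thin loci (seeded) to keep the K scan tractable
            rng = np.random.default_rng(self._seed())
            sub = np.sort(rng.choice(g.n_loci, cfg.cv_locus_cap,
                                     replace=False))
            g_cv = g.take_loci(sub)
        cv = popstruct.choose_K(
            g_cv, K_range=cfg.K_range, mask_fraction=cfg.mask_fraction,
            seed=self._seed(), sites=sites, n_restarts=cfg.n_restarts,
        )
        cv.to_csv(self.outdir / "choose_K.csv", index=False)
        K_opt = popstruct.select_K(cv)
        model = popstruct.estimate_ancestry(
            g, K_opt, seed=self._seed(), n_restarts=cfg.n_restarts
        )
        pd.DataFrame(
            model.Q, index=g.individual_ids,
            columns=[f"q{k}" for k in range(K_opt)],
        ).to_csv(self.outdir / "Q_matrix.csv")
        gi = popstruct.impute_genotypes(g, model)
        genio.write_genotypes(gi, self.outdir / "genotypes_imputed.tsv")

        if K_opt >= 2:
            Qg, modal = popstruct.interpolate_Q(model, sites, self._env)
        else:
            modal = np.ones(self._env.shape)
        genio.write_raster(
            self.outdir / "modal_group.asc", modal.astype(float),
            self._env.xllcorner, self._env.yllcorner, self._env.cellsize,
        )

        zones = sites.ordered_for(g.individual_ids)["zone"].to_numpy()
        am = popstruct.amova(g, zones, n_perm=cfg.n_perm, seed=self._seed())
        gl = popstruct.global_fst(g, zones)
        pw = popstruct.pairwise_fst(g, zones, n_perm=min(cfg.n_perm, 99),
                                    seed=self._seed())
        pw.pairwise_fst.to_csv(self.outdir / "pairwise_fst.csv")
        pd.DataFrame(
            {
                "sigma_among": [am.amova_components[0]],
                "sigma_within": [am.amova_components[1]],
                "phi_st": [am.phi_st],
                "p": [am.p_perm],
                "global_fst_nei": [gl.global_fst],
            }
        ).to_csv(self.outdir / "amova.csv", index=False)

        D = popstruct.geodesic_matrix(sites.zone_coords())
        ibd = popstruct.ibd_fit(pw.pairwise_fst.to_numpy(), D.to_numpy(),
                                n_perm=cfg.n_perm, seed=self._seed())
        pd.DataFrame(
            {
                "mantel_r": [ibd.mantel_r],
                "mantel_p": [ibd.mantel_p],
                "slope_fst_per_100km": [ibd.slope_per_100km],
                "r2": [ibd.r2],
            }
        ).to_csv(self.outdir / "ibd.csv", index=False)

        self._record(
            "structure", K_opt=K_opt, phi_st=round(am.phi_st, 6),
            global_fst=round(gl.global_fst, 6),
            mantel_r=round(ibd.mantel_r, 4),
        )
        self._K_opt, self._ancestry, self._gi = K_opt, model, gi
        return model

    def stage_select_env(self):
        cfg = self.config
        sites_ord = self._sites.ordered_for(self._gf.individual_ids)
        env_ind = self._env.site_values["present"].loc[
            sites_ord["site_id"]
        ].reset_index(drop=True)
        Y = self._gi.values - self._gi.values.mean(axis=0)
        trace = ordination.forward_select(
            Y, env_ind, alpha=cfg.alpha_forward,
            n_perm=cfg.n_perm_forward, seed=self._seed(),
        )
        trace.to_csv(self.outdir / "forward_selection.csv", index=False)
        selected = list(trace["variable"])
        if not selected:
            logger.warning("forward selection kept no variables; using all")
            selected = list(env_ind.columns)
        clusters = ordination.varclus_spearman(
            env_ind[selected] if len(selected) > 1 else env_ind,
            cut=cfg.varclus_cut,
        )
        # one representative per branch: the first selected member
        rep: dict[int, str] = {}
        for var in selected if len(selected) > 1 else list(env_ind.columns):
            rep.setdefault(clusters[var], var)
        final = [v for v in selected if rep.get(clusters.get(v, -1)) == v] \
            if len(selected) > 1 else selected
        pd.DataFrame(
            {"variable": list(clusters), "cluster": list(clusters.values()),
             "kept": [v in final for v in clusters]}
        ).to_csv(self.outdir / "varclus.csv", index=False)

        # Table-2-style variance partitioning
        geo = sites_ord[["longitude", "latitude"]].reset_index(drop=True)
        Qdf = pd.DataFrame(
            self._ancestry.Q[:, : max(self._K_opt - 1, 1)],
            columns=[f"q{k}" for k in range(max(self._K_opt - 1, 1))],
        )
        try:
            part = ordination.variance_partition(
                Y, env_ind[final], geo, Qdf, n_perm=cfg.n_perm,
                seed=self._seed(),
            )
            part.table.to_csv(self.outdir / "variance_partition.csv")
        except ValueError as exc:
            logger.warning("variance partition skipped: %s", exc)
        self._record("select_env", selected=selected, final=final)
        self._env_vars = final
        self._env_ind = env_ind
        return final

    def stage_gea(self):
        cfg = self.config
        env_final = self._env_ind[self._env_vars]
        Qcond = pd.DataFrame(
            self._ancestry.Q[:, : max(self._K_opt - 1, 1)],
            columns=[f"q{k}" for k in range(max(self._K_opt - 1, 1))],
        )
        Y = self._gi.values - self._gi.values.mean(axis=0)
        rda_model = ordination.rda_fit(Y, env_final, Qcond)
        cands = gea.run_all(
            self._gi, env_final, rda_model, K_latent=self._K_opt,
            n_pcs=cfg.n_pcs, k_axes=min(cfg.k_axes, rda_model.n_axes),
            alpha=cfg.alpha_gea,
        )
        ids = self._gf.locus_meta["id"]
        out = pd.DataFrame({"id": ids})
        for name, res in cands.methods.items():
            out[f"{name}_stat"] = res.statistic
            out[f"{name}_q"] = res.q
            out[f"{name}_hit"] = res.hits
        out["consensus"] = np.isin(np.arange(len(ids)), cands.consensus_idx)
        out.to_csv(self.outdir / "gea_candidates.csv", index=False)
        self._record("gea", **cands.counts())
        self._candidates = cands
        return cands

    def stage_offset(self):
        cfg = self.config
        mode = cfg.candidate_mode
        if mode == "consensus":
            idx = self._candidates.consensus_idx
        elif mode == "union":
            idx = self._candidates.union_idx()
        elif mode == "all":
            idx = np.arange(self._gf.n_loci)
        else:
            raise ValueError(f"unknown candidate mode {mode!r}")
        if len(idx) == 0:
            logger.warning("empty %s candidate set; falling back to union",
                           mode)
            idx = self._candidates.union_idx()
        if len(idx) == 0:
            raise RuntimeError("stage offset: no candidate loci available")

        freqs = offset.site_allele_freqs(self._gi, self._sites, idx)
        env_sites = self._env.site_values["present"][self._env_vars]
        model = offset.enriched_rda(freqs, env_sites)
        surf = offset.temporal_offset(
            model, self._env, axes=tuple(cfg.axes), weighting=cfg.weighting,
            threshold=cfg.zprime_threshold,
            max_pairs=cfg.max_reference_pairs, seed=self._seed(),
        )
        xy = (self._env.xllcorner, self._env.yllcorner, self._env.cellsize)
        genio.write_raster(self.outdir / "offset_raw.asc", surf.raw, *xy)
        genio.write_raster(self.outdir / "offset_zprime.asc", surf.z, *xy)
        genio.write_raster(self.outdir / "offset_mask.asc",
                           surf.mask.astype(float), *xy)
        pd.DataFrame(
            {
                "n_reference": [len(surf.reference.values)],
                "ref_median": [float(np.median(surf.reference.values))],
                "ref_p95": [float(np.percentile(surf.reference.values, 95))],
                "n_above_threshold": [surf.n_flagged()],
            }
        ).to_csv(self.outdir / "offset_summary.csv", index=False)
        self._record("offset", n_candidates=int(len(idx)),
                     n_above_threshold=surf.n_flagged(), mode=mode)
        self._enriched, self._surface = model, surf
        return surf

    def stage_donor(self):
        cfg = self.config
        surf = self._surface
        z = np.where(np.isfinite(surf.z), surf.z, -np.inf)
        recipient = np.unravel_index(int(z.argmax()), z.shape)
        donor = offset.donor_offset(
            self._enriched, self._env, recipient, surf.reference,
            axes=tuple(cfg.axes), weighting=cfg.weighting,
            threshold=cfg.zprime_threshold,
        )
        xy = (self._env.xllcorner, self._env.yllcorner, self._env.cellsize)
        genio.write_raster(self.outdir / "donor_zprime.asc", donor.z, *xy)
        ranking = offset.donor_ranking(donor)
        ranking.head(1000).to_csv(self.outdir / "donor_ranking.csv",
                                  index=False)
        self._record("donor", recipient=list(map(int, recipient)),
                     n_suitable=int(ranking["suitable"].sum()))
        return donor

    def run_all(self) -> dict:
        order = [
            ("simulate", self.stage_simulate),
            ("filter", self.stage_filter),
            ("structure", self.stage_structure),
            ("select_env", self.stage_select_env),
            ("gea", self.stage_gea),
            ("offset", self.stage_offset),
            ("donor", self.stage_donor),
        ]
        for name, fn in order:
            try:
                self._timed(name, fn)
            except Exception as exc:
                raise RuntimeError(f"stage {name} failed: {exc}") from exc
        self.config.to_yaml(self.outdir / "config.yaml")
        return self.manifest


def _load_env_dir(raster_dir: Path, sites) -> genio.EnvLayerSet:
    """Load ``env_<var>_<period>.asc`` rasters from a directory."""
    grids: dict[str, dict[str, np.ndarray]] = {}
    header = None
    for path in sorted(raster_dir.glob("env_*_*.asc")):
        stem = path.stem[len("env_"):]
        var, period = stem.rsplit("_", 1)
        grid, hdr = genio.read_raster(path)
        header = header or hdr
        grids.setdefault(var, {})[period] = grid
    if not grids:
        raise FileNotFoundError(f"no env_*_*.asc rasters in {raster_dir}")
    env = genio.EnvLayerSet(
        variables=sorted(grids),
        grids=grids,
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
        site_values={},
        standardization=pd.DataFrame(
            {"mean": 0.0, "sd": 1.0}, index=sorted(grids)
        ),
    )
    synthdata.attach_site_values(env, sites)
    return env


def run(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns the manifest."""
    return Pipeline(config).run_all()
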