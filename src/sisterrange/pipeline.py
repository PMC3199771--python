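"""End-to-end analysis pipeline.

Runs the full sister-species analysis in the order the science dictates:
sister-pair extraction and filtering, range construction under both buffer
policies, allopatric/sympatric classification, the sister vs non-sister
overlap sign test, age-range correlation, the quantile-regression test of
peripatric speciation, contrast regressions (body size on range size, and the
factorial spatial model), the climatic-niche covariate, and the
richness-contrast diversification test.  Everything is a pure function of
(inputs, options, seed); outputs are CSV tables plus one JSON summary, so a
rerun on the same inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparative_stats as cs
from . import climate_niche as cn
from . import diversification as dv
from . import range_geometry as rg
from . import sister_pairs as sp
from .phylo_io import (PhyloTree, read_climate_table, read_locality_table,
                       read_trait_table, read_tree)
from .synth import SynthDataset

__all__ = ["PipelineConfig", "AnalysisOptions", "run_pipeline", "run_analysis"]

log = logging.getLogger(__name__)


@dataclass
class AnalysisOptions:
    min_support: float = 95.0
    policies: tuple[str, ...] = ("RSA", "RSB")
    exclusions: tuple[str, ...] = ()
    correlation: str = "pearson"      # age-range correlation type
    sign_reference: str = "median"    # sister vs non-sister comparison point
    tau: float = 0.9                  # quantile-regression quantile
    log10_range_for_quantile: bool = True
    log10_svl_for_rrd: bool = True
    climate_covariance: str = "pooled"


@dataclass
class PipelineConfig:
    tree_time: str
    tree_subst: str
    traits: str
    localities: str
    climate: str | None = None
    out_dir: str = "sisterrange_out"
    seed: int = 0
    options: AnalysisOptions = field(default_factory=AnalysisOptions)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        opts = AnalysisOptions(**raw.pop("options", {}))
        return cls(options=opts, **raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Load the configured files and run the full analysis, writing outputs."""
    dataset = SynthDataset(
        tree_time=read_tree(config.tree_time),
        tree_subst=read_tree(config.tree_subst),
        traits=read_trait_table(config.traits),
        localities=read_locality_table(config.localities),
        climate=read_climate_table(config.climate) if config.climate else None,
    )
    return run_analysis(dataset, config.options, out_dir=config.out_dir)


def run_analysis(
    ds: SynthDataset,
    options: AnalysisOptions | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run every stage on an in-memory dataset; optionally write reports.

    Returns the summary dictionary (also written as ``summary.json`` when
    ``out_dir`` is given, alongside the per-stage CSV tables).
    """
    opt = options or AnalysisOptions()
    summary: dict = {"options": asdict(opt)}
    tables: dict[str, pd.DataFrame] = {}

    # -- sister pairs ------------------------------------------------------
    species_with_data = (set(ds.traits["species"])
                         & set(ds.localities["species"]))
    pairs = sp.find_sister_pairs(
        ds.tree_subst,
        min_support=opt.min_support,
        exclusion_list=opt.exclusions,
        species_with_data=species_with_data,
    )
    sp.pair_ages(pairs, ds.tree_time)
    included = [p for p in pairs if not p.excluded]
    tables["sister_pairs"] = sp.pairs_to_frame(pairs)
    ages = np.array([p.age for p in included])
    summary["pairs"] = {
        "n_cherries": len(pairs),
        "n_included": len(included),
        "mean_age_ma": float(ages.mean()) if len(included) else None,
    }
    if len(included) >= 5 and np.ptp(ages) > 0:
        d, p = cs.ks_normality(ages)
        summary["pairs"]["age_ks_D"] = d
        summary["pairs"]["age_ks_p"] = p

    # -- ranges, per policy ------------------------------------------------
    range_sets = {}
    centroid_dist = None
    for policy in opt.policies:
        rset = rg.build_range_set(ds.localities, policy)
        range_sets[policy] = rset
        tables[f"ranges_{policy.lower()}"] = pd.DataFrame(
            {
                "species": rset.species,
                "policy": policy,
                "area_km2": [rset[s].area_km2 for s in rset.species],
                "centroid_x_km": [rset[s].centroid_km[0] for s in rset.species],
                "centroid_y_km": [rset[s].centroid_km[1] for s in rset.species],
                "n_localities": [rset[s].n_localities for s in rset.species],
                "construction": [rset[s].construction for s in rset.species],
            }
        )
        if centroid_dist is None:
            # centroids do not depend on the buffer radius
            centroid_dist = rg.centroid_distance_matrix(rset)

    # -- climatic covariate ------------------------------------------------
    climatic_dist = None
    if ds.climate is not None:
        pca = cn.pca_varimax(ds.climate)
        climatic_dist = cn.mahalanobis_matrix(
            pca.scores, pca.species, covariance=opt.climate_covariance)
        summary["climate"] = {
            "n_retained_pcs": int(pca.eigenvalues.size),
            "eigenvalues": [float(v) for v in pca.eigenvalues],
        }

    policy_stats: dict = {}
    for policy, rset in range_sets.items():
        stats_p: dict = {}
        overlap = rg.overlap_matrix(rset)
        labels = rg.classify_pairs(included, rset)
        n_allo = sum(v == "allopatric" for v in labels.values())
        n_symp = sum(v == "sympatric" for v in labels.values())
        stats_p["classification"] = {
            "allopatric": n_allo,
            "sympatric": n_symp,
            "pct_allopatric": 100.0 * n_allo / max(len(labels), 1),
        }
        pair_keys = [(p.species_a, p.species_b) for p in included]
        sis_overl = np.array([overlap.loc[a, b] for a, b in pair_keys])
        stats_p["mean_overlap_pct"] = float(sis_overl.mean()) if len(included) else None
        symp_vals = sis_overl[sis_overl > 0]
        stats_p["mean_overlap_pct_sympatric"] = (
            float(symp_vals.mean()) if symp_vals.size else None)

        nonsis = cs.nonsister_overlap_values(overlap, pair_keys)
        try:
            z, p = cs.sign_test_overlap(sis_overl, nonsis,
                                        reference=opt.sign_reference)
            stats_p["sign_test"] = {"Z": z, "p": p}
        except ValueError as exc:
            stats_p["sign_test"] = {"error": str(exc)}

        try:
            r, p = cs.age_range_correlation(ages, sis_overl,
                                            method=opt.correlation)
            stats_p["age_range_correlation"] = {"r": r, "p": p}
        except ValueError as exc:
            stats_p["age_range_correlation"] = {"error": str(exc)}
        policy_stats[policy] = stats_p

    # -- contrast table ----------------------------------------------------
    contrasts = cs.build_contrast_table(
        included, ds.traits, range_sets,
        centroid_distances=centroid_dist,
        climatic_distances=_pairwise_lookup(climatic_dist),
    )
    tables["contrasts"] = contrasts

    # -- quantile regression (peripatric prediction) -----------------------
    for policy in opt.policies:
        key = policy.lower()
        stats_p = policy_stats[policy]
        sizes = (contrasts[[f"area_{key}_a", f"area_{key}_b"]]
                 .mean(axis=1).to_numpy())
        if opt.log10_range_for_quantile:
            sizes = np.log10(sizes)
        try:
            slope, icpt = cs.quantile_regression(sizes, ages, tau=opt.tau)
            stats_p["quantile_range_size"] = {"slope": slope, "intercept": icpt}
            slope, icpt = cs.quantile_regression(
                contrasts[f"abs_c_{key}"].to_numpy(), ages, tau=opt.tau)
            stats_p["quantile_abs_contrast"] = {"slope": slope, "intercept": icpt}
        except (ValueError, RuntimeError) as exc:
            stats_p["quantile_regression_error"] = str(exc)

        # -- body size predicting range size (through-origin) --------------
        try:
            reg = cs.regression_through_origin(
                contrasts[f"c_{key}"],
                pd.DataFrame({"c_svl": contrasts["c_svl"]}))
            stats_p["svl_on_range_regression"] = _reg_summary(reg)
            tables[f"regression_svl_on_{key}"] = reg.to_frame()
        except ValueError as exc:
            stats_p["svl_on_range_regression"] = {"error": str(exc)}

        # -- factorial spatial model ---------------------------------------
        if climatic_dist is not None and len(contrasts) >= 9:
            try:
                reg = cs.factorial_regression(
                    contrasts[f"abs_c_{key}"], ages,
                    contrasts["centroid_distance_km"],
                    contrasts["climatic_distance"])
                stats_p["factorial_regression"] = _reg_summary(reg)
            except ValueError as exc:
                stats_p["factorial_regression"] = {"error": str(exc)}
    summary["policies"] = policy_stats

    # -- factorial model for SVL contrasts ---------------------------------
    if climatic_dist is not None and len(contrasts) >= 9:
        try:
            reg = cs.factorial_regression(
                contrasts["abs_c_svl"], ages,
                contrasts["centroid_distance_km"],
                contrasts["climatic_distance"])
            summary["factorial_svl"] = _reg_summary(reg)
        except ValueError as exc:
            summary["factorial_svl"] = {"error": str(exc)}

    # -- richness contrasts (diversification) ------------------------------
    trait_map = dict(zip(ds.traits["species"], ds.traits["svl_mm"]))
    rcs = dv.richness_contrasts(ds.tree_subst, trait_map,
                                log10_trait=opt.log10_svl_for_rrd)
    tables["richness_contrasts"] = dv.contrasts_to_frame(rcs)
    if len(rcs) >= 3:
        reg, r, p_r = dv.diversification_test(rcs)
        summary["diversification"] = {**_reg_summary(reg), "r": r, "p_r": p_r,
                                      "slope": float(reg.params.iloc[0])}

    if out_dir is not None:
        _write_outputs(Path(out_dir), summary, tables, centroid_dist,
                       climatic_dist)
    return summary


def _pairwise_lookup(matrix: pd.DataFrame | None) -> pd.DataFrame | None:
    return matrix


def _reg_summary(reg: cs.RegressionResult) -> dict:
    return {
        "multiple_r2": reg.r2,
        "ss_model": reg.ss_model,
        "ms_model": reg.ms_model,
        "ss_residual": reg.ss_residual,
        "ms_residual": reg.ms_residual,
        "F": reg.F,
        "p": reg.p,
        "n": reg.n,
    }


def _write_outputs(out: Path, summary: dict, tables: dict,
                   centroid_dist: pd.DataFrame | None,
                   climatic_dist: pd.DataFrame | None) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    if centroid_dist is not None:
        centroid_dist.to_csv(out / "centroid_distances_km.csv")
    if climatic_dist is not None:
        climatic_dist.to_csv(out / "climatic_distances.csv")
    (out / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=1, default=float) + "\n")
    log.info("pipeline outputs written to %s", out)
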