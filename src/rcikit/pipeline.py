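"""End-to-end orchestration: design -> data -> fits -> RCI -> correlation.

Every source of randomness is seeded from one master seed through a fixed
:class:`numpy.random.SeedSequence` spawn tree:

    SeedSequence(master) -> [data, analysis]
    data      -> [generation seed, mortality seed]
    analysis  -> one child per (species, soil_country), in the sorted order
                 of all combinations implied by the design config

Analysis-stage seeds therefore do not depend on whether records were
simulated or read from a file, so an input-path run on a previously
simulated CSV reproduces the simulate-mode results bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
import pandas as pd

from rcikit import __version__
from rcikit.compare import CorrelationResult, build_comparison_table, pearson_correlation
from rcikit.design import (
    DesignConfig,
    INTRODUCED,
    SOIL_COUNTRIES,
    build_study_design,
    design_to_frame,
    paired_pairings,
    single_provenances,
)
from rcikit.errors import ConfigurationError
from rcikit.growth import GrowthFit, cell_label, fit_growth_model, test_provenance_effect
from rcikit.rci import (
    DEFAULT_DRAWS,
    RCIDiffSummary,
    RCISummary,
    diffs_to_frame,
    rci_difference,
    rci_from_draws,
    simulate_fixed_effects,
    summarize_rci,
)
from rcikit.records import read_records, write_records
from rcikit.simulate import TrueParams, apply_mortality, default_true_params, generate_dataset

logger = logging.getLogger(__name__)

MIN_DRAWS = 1000


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``params`` (simulate mode) and ``input_path`` (load mode)
    must be set.
    """

    design: DesignConfig = field(default_factory=DesignConfig)
    params: TrueParams | None = None
    input_path: str | None = None
    S: int = DEFAULT_DRAWS
    seed: int = 0
    use_absolute: bool = True
    log_scale: bool = False
    nod_as_factor: bool = False

    def __post_init__(self) -> None:
        if (self.params is None) == (self.input_path is None):
            raise ConfigurationError(
                "exactly one of params (simulate mode) and input_path must be set"
            )
        if self.S < MIN_DRAWS:
            raise ConfigurationError(f"S must be >= {MIN_DRAWS}; got {self.S}")


@dataclass
class RunResult:
    design_frame: pd.DataFrame
    records: pd.DataFrame
    fits: dict[tuple[str, str], GrowthFit]
    rci_summaries: pd.DataFrame
    rci_diff_summaries: list[RCIDiffSummary]
    comparison: pd.DataFrame
    correlation: CorrelationResult
    provenance_tests: pd.DataFrame
    manifest: dict


def derive_seeds(master_seed: int, design: DesignConfig) -> dict:
    """Fixed seed-derivation tree; see module docstring."""
    root = np.random.SeedSequence(master_seed)
    data_ss, analysis_ss = root.spawn(2)
    gen_ss, mort_ss = data_ss.spawn(2)
    combos = sorted((sp, soil) for soil in SOIL_COUNTRIES for sp in design.species)
    fit_children = analysis_ss.spawn(len(combos))
    return {
        "generate": int(gen_ss.generate_state(1)[0]),
        "mortality": int(mort_ss.generate_state(1)[0]),
        "analysis": {
            combo: int(child.generate_state(1)[0])
            for combo, child in zip(combos, fit_children)
        },
    }


def _rci_pairings(soil: str, design: DesignConfig) -> list[tuple[str, str]]:
    """Pairings whose focal-alone cells exist in the single-pot design.

    Under the strict-formula reading, native-range soils carry a paired
    treatment whose native provenance was never grown alone there; those
    pairings cannot yield an RCI contrast and are skipped with a warning.
    """
    singles = set(single_provenances(soil))
    usable = []
    for intro, native in paired_pairings(soil, design.mode):
        if native in singles:
            usable.append((intro, native))
        else:
            logger.warning(
                "skipping pairing %sx%s in %s soil: provenance %s has no single-grown cell",
                intro, native, soil, native,
            )
    return usable


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> RunResult:
    """Execute all stages in order and optionally write every output table.

    Stage errors propagate with the offending cell named by the underlying
    module; the manifest records config, seeds, version and per-stage row
    counts.
    """
    seeds = derive_seeds(config.seed, config.design)

    design = build_study_design(config.design)
    design_frame = design_to_frame(design)
    logger.info("stage design: %d pots", len(design))

    if config.params is not None:
        params = replace(config.params, seed=seeds["generate"])
        records = generate_dataset(design, params)
        records = apply_mortality(records, params.mortality_rate, seeds["mortality"])
        logger.info("stage generate: %d plants after mortality", len(records))
    else:
        records = read_records(config.input_path)
        logger.info("stage read: %d plants from %s", len(records), config.input_path)

    fits: dict[tuple[str, str], GrowthFit] = {}
    prov_rows = []
    rci_rows = []
    diff_summaries: list[RCIDiffSummary] = []
    for (species, soil) in sorted(seeds["analysis"]):
        subset = records[(records["species"] == species) & (records["soil_country"] == soil)]
        if subset.empty:
            continue
        expected = list(single_provenances(soil))
        for intro, native in paired_pairings(soil, config.design.mode):
            if native in expected:
                expected += [cell_label(intro, native), cell_label(native, intro)]
        fit = fit_growth_model(
            subset, include_paired=True,
            nod_as_factor=config.nod_as_factor,
            expected_cells=tuple(expected),
        )
        fits[(species, soil)] = fit

        test = test_provenance_effect(subset, method="lrt_ml", nod_as_factor=config.nod_as_factor)
        f_test = test_provenance_effect(subset, method="approx_f", nod_as_factor=config.nod_as_factor)
        prov_rows.append(
            {
                "species": species,
                "soil_country": soil,
                "lrt_statistic": test.statistic,
                "lrt_df": test.df_num,
                "lrt_p": test.p_value,
                "f_statistic": f_test.statistic,
                "f_df_num": f_test.df_num,
                "f_df_den": f_test.df_den,
                "f_p": f_test.p_value,
            }
        )

        draws = simulate_fixed_effects(fit, S=config.S, seed=seeds["analysis"][(species, soil)])
        for intro, native in _rci_pairings(soil, config.design):
            d_intro = rci_from_draws(draws, fit, intro, cell_label(intro, native))
            d_native = rci_from_draws(draws, fit, native, cell_label(native, intro))
            for d in (d_intro, d_native):
                s = summarize_rci(d)
                rci_rows.append(
                    {
                        "species": species,
                        "soil_country": soil,
                        "index_label": s.index_label,
                        "mean": s.mean,
                        "ci50_lower": s.ci50[0],
                        "ci50_upper": s.ci50[1],
                        "ci95_lower": s.ci95[0],
                        "ci95_upper": s.ci95[1],
                    }
                )
            diff_summaries.append(
                rci_difference(
                    d_intro, d_native,
                    species=species, soil_country=soil, native_partner=native,
                )
            )
    logger.info("stage fit: %d models; stage rci: %d contrasts", len(fits), len(diff_summaries))

    rci_summaries = pd.DataFrame(rci_rows)
    comparison = build_comparison_table(
        fits, diff_summaries, use_absolute=config.use_absolute, log_scale=config.log_scale
    )
    correlation = pearson_correlation(comparison["growth_diff"], comparison["rci_diff"])
    logger.info(
        "stage correlate: r=%.3f p=%.4f n=%d", correlation.r, correlation.p_value, correlation.n
    )

    manifest = {
        "package_version": __version__,
        "master_seed": config.seed,
        "derived_seeds": {
            "generate": seeds["generate"],
            "mortality": seeds["mortality"],
            "analysis": {f"{sp}:{soil}": s for (sp, soil), s in seeds["analysis"].items()},
        },
        "config": {
            "design_mode": config.design.mode,
            "species": list(config.design.species),
            "sites_per_country": config.design.sites_per_country,
            "replicates": config.design.replicates,
            "mode": "simulate" if config.params is not None else "input_path",
            "input_path": config.input_path,
            "S": config.S,
            "use_absolute": config.use_absolute,
            "log_scale": config.log_scale,
            "nod_as_factor": config.nod_as_factor,
        },
        "row_counts": {
            "design": len(design_frame),
            "records": len(records),
            "fits": len(fits),
            "rci_indices": len(rci_summaries),
            "rci_contrasts": len(diff_summaries),
            "comparison": len(comparison),
        },
        "correlation": {"r": correlation.r, "p_value": correlation.p_value, "n": correlation.n},
    }

    result = RunResult(
        design_frame=design_frame,
        records=records,
        fits=fits,
        rci_summaries=rci_summaries,
        rci_diff_summaries=diff_summaries,
        comparison=comparison,
        correlation=correlation,
        provenance_tests=pd.DataFrame(prov_rows),
        manifest=manifest,
    )
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def write_outputs(result: RunResult, outdir: str | Path) -> None:
    """Write all pipeline tables as tidy CSV plus a JSON manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.17g"
    result.design_frame.to_csv(out / "design.csv", index=False)
    write_records(result.records, out / "records.csv")
    fit_dir = out / "fits"
    fit_dir.mkdir(exist_ok=True)
    fit_report: dict = {}
    for (species, soil), fit in sorted(result.fits.items()):
        stem = f"{species}_{soil}"
        fit.summary_frame().to_csv(fit_dir / f"{stem}_coefficients.csv", index=False, float_format=fmt)
        vcov = pd.DataFrame(fit.vcov_fixed, index=fit.coef_labels, columns=fit.coef_labels)
        vcov.to_csv(fit_dir / f"{stem}_vcov.csv", float_format=fmt)
        fit_report[stem] = {
            "sigma_site_hat": fit.sigma_site_hat,
            "sigma_resid_hat": fit.sigma_resid_hat,
            "loglik_reml": fit.loglik_reml,
            "loglik_ml": fit.loglik_ml,
            "n_obs": fit.n_obs,
            "fitted_by": fit.fitted_by,
        }
    (fit_dir / "fit_report.json").write_text(json.dumps(fit_report, indent=2, sort_keys=True))
    result.provenance_tests.to_csv(out / "provenance_tests.csv", index=False, float_format=fmt)
    result.rci_summaries.to_csv(out / "rci_summaries.csv", index=False, float_format=fmt)
    diffs_to_frame(result.rci_diff_summaries).to_csv(out / "rci_diffs.csv", index=False, float_format=fmt)
    result.comparison.to_csv(out / "comparison.csv", index=False, float_format=fmt)
    pd.DataFrame(
        [{"r": result.correlation.r, "p_value": result.correlation.p_value, "n": result.correlation.n}]
    ).to_csv(out / "correlation.csv", index=False, float_format=fmt)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2, sort_keys=True))
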