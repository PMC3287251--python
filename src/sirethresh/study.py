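"""Factorial simulation study: ECP levels x g-prior weights x sire variances.

The full design is 5 ECP targets (5, 10, 20, 30, 75% of classes extreme)
x 4 priors (normal prior = g 0, and g-priors with weight 0.05, 0.10, 0.15)
x 2 true sire variances (0.05, 0.02) x 5 replicate datasets, with 5000
records on 500 sires in 200 fixed-effect classes and 75k-iteration chains.
``scale_factor`` shrinks records, pedigree, classes and chain length
proportionally (with floors) for desk-scale runs; per-class and per-sire
record counts are preserved so the ECP mechanics are unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import gibbs, posterior, simulator

__all__ = [
    "ECP_LEVELS",
    "G_WEIGHTS",
    "PRIOR_LABELS",
    "ScenarioSpec",
    "study_dimensions",
    "calibrate_scenario_bounds",
    "run_scenario",
    "reproduce_tables",
]

ECP_LEVELS: tuple[float, ...] = (0.05, 0.10, 0.20, 0.30, 0.75)
G_WEIGHTS: tuple[float, ...] = (0.0, 0.05, 0.10, 0.15)

#: Field-standard labels for the four priors (NP = normal prior on all
#: classes, i.e. flat treatment of ECP classes; xG = x% g-prior weight).
PRIOR_LABELS: dict[float, str] = {0.0: "NP", 0.05: "5G", 0.10: "10G", 0.15: "15G"}

_FULL = dict(
    n_records=5000,
    n_classes=200,
    n_base=50,
    n_per_generation=150,
    n_generations=3,
    n_iterations=75_000,
    burn_in=25_000,
)


def study_dimensions(scale_factor: float) -> dict[str, int]:
    """Problem sizes at a given scale of the full design (floors applied)."""
    if not 0.0 < scale_factor <= 1.0:
        raise ValueError("scale_factor must lie in (0, 1]")
    f = scale_factor
    dims = dict(
        n_records=max(200, round(_FULL["n_records"] * f)),
        n_classes=max(8, round(_FULL["n_classes"] * f)),
        n_base=max(2, round(_FULL["n_base"] * f)),
        n_per_generation=max(1, round(_FULL["n_per_generation"] * f)),
        n_generations=_FULL["n_generations"],
        n_iterations=max(2000, round(_FULL["n_iterations"] * f)),
        burn_in=max(500, round(_FULL["burn_in"] * f)),
    )
    if dims["burn_in"] >= dims["n_iterations"]:
        dims["burn_in"] = dims["n_iterations"] // 3
    return dims


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the study design (a single ECP level and sire variance)."""

    ecp_target: float
    sigma_u2_true: float
    g_weights: tuple[float, ...] = G_WEIGHTS
    n_replicates: int = 5
    scale_factor: float = 1.0
    n_iterations: int | None = None  # override the scaled default
    burn_in: int | None = None

    def dimensions(self) -> dict[str, int]:
        dims = study_dimensions(self.scale_factor)
        if self.n_iterations is not None:
            dims["n_iterations"] = self.n_iterations
        if self.burn_in is not None:
            dims["burn_in"] = self.burn_in
        if not 0 <= dims["burn_in"] < dims["n_iterations"]:
            raise ValueError("burn_in must be smaller than n_iterations")
        return dims


def _seedseq(master_seed: int, *key: int) -> np.random.SeedSequence:
    """Counter-based substream: (master, scenario, replicate, role, ...)."""
    return np.random.SeedSequence(entropy=(int(master_seed),) + tuple(int(k) for k in key))


def _scenario_key(spec: ScenarioSpec) -> tuple[int, int]:
    return int(round(spec.ecp_target * 1000)), int(round(spec.sigma_u2_true * 10_000))


def calibrate_scenario_bounds(spec: ScenarioSpec, master_seed: int) -> tuple[float, float]:
    """Calibrate the uniform class-effect bounds once per scenario.

    Within a scenario only the replicate seed changes, never the bounds, so
    calibration is keyed on (master_seed, ECP target, sigma_u2) alone.
    """
    dims = spec.dimensions()
    key = _scenario_key(spec)
    records_per_class = max(1, dims["n_records"] // dims["n_classes"])
    return simulator.calibrate_fixed_effect_bounds(
        spec.ecp_target,
        dims["n_classes"],
        records_per_class,
        spec.sigma_u2_true,
        _seedseq(master_seed, *key, 0),
    )


def run_scenario(
    spec: ScenarioSpec,
    master_seed: int,
    *,
    bounds: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate replicates and fit every g-prior weight to each of them.

    Every prior is fit to the *same* dataset within a replicate, enabling
    paired comparisons across priors.  Returns (summary, detail): `summary`
    has one row per g weight with replicate-averaged cells; `detail` has one
    row per (replicate, g weight).
    """
    dims = spec.dimensions()
    key = _scenario_key(spec)
    if bounds is None:
        bounds = calibrate_scenario_bounds(spec, master_seed)
    rows = []
    for rep in range(spec.n_replicates):
        ped = simulator.build_pedigree(
            dims["n_base"],
            dims["n_per_generation"],
            dims["n_generations"],
            _seedseq(master_seed, *key, rep, 1),
        )
        dataset, truth = simulator.simulate_dataset(
            ped,
            dims["n_records"],
            dims["n_classes"],
            bounds,
            spec.sigma_u2_true,
            _seedseq(master_seed, *key, rep, 2),
        )
        ecp_frac = simulator.ecp_fraction(dataset)
        incidence = float(dataset.y.mean())
        for g in spec.g_weights:
            cfg = gibbs.GibbsConfig(
                g_weight=g,
                S2_u=spec.sigma_u2_true,
                n_iterations=dims["n_iterations"],
                burn_in=dims["burn_in"],
                seed=int(
                    _seedseq(
                        master_seed, *key, rep, 3, int(round(g * 1000))
                    ).generate_state(1)[0]
                    % 2**31
                ),
            )
            res = gibbs.run_chain(dataset, ped, cfg)
            summ = posterior.summarize_chain(res.sigma_u2_draws)
            bias = posterior.bias_report(summ, spec.sigma_u2_true)
            rows.append(
                dict(
                    ecp_target=spec.ecp_target,
                    sigma_u2_true=spec.sigma_u2_true,
                    replicate=rep,
                    g_weight=g,
                    prior=PRIOR_LABELS.get(g, f"{g:g}G"),
                    sigma_u2_mean=summ.mean,
                    sigma_u2_sd=summ.sd,
                    hpd_lower=summ.hpd_lower,
                    hpd_upper=summ.hpd_upper,
                    relative_bias=bias.relative_bias,
                    truth_outside_hpd=bias.biased,
                    pearson_fixed=posterior.pearson_true_vs_estimated(
                        truth.beta_true, res.beta_mean
                    ),
                    pearson_sire=posterior.pearson_true_vs_estimated(
                        truth.s_true, res.s_mean
                    ),
                    ecp_fraction=ecp_frac,
                    incidence=incidence,
                    n_records=dims["n_records"],
                    n_iterations=dims["n_iterations"],
                )
            )
    detail = pd.DataFrame(rows)
    summary = detail.groupby(
        ["ecp_target", "sigma_u2_true", "g_weight", "prior"], as_index=False
    ).agg(
        sigma_u2_mean=("sigma_u2_mean", "mean"),
        sigma_u2_mean_rep_sd=("sigma_u2_mean", "std"),
        sigma_u2_sd=("sigma_u2_sd", "mean"),
        hpd_lower=("hpd_lower", "mean"),
        hpd_upper=("hpd_upper", "mean"),
        relative_bias=("relative_bias", "mean"),
        pearson_fixed=("pearson_fixed", "mean"),
        pearson_sire=("pearson_sire", "mean"),
        ecp_fraction=("ecp_fraction", "mean"),
        incidence=("incidence", "mean"),
        n_replicates=("replicate", "count"),
    )
    summary = summary.sort_values(["sigma_u2_true", "ecp_target", "g_weight"]).reset_index(
        drop=True
    )
    return summary, detail


def reproduce_tables(
    master_seed: int,
    scale_factor: float = 1.0,
    out_dir: str | Path | None = None,
    *,
    sigma_values: Sequence[float] = (0.05, 0.02),
    n_replicates: int = 5,
    ecp_levels: Sequence[float] = ECP_LEVELS,
    g_weights: Sequence[float] = G_WEIGHTS,
    n_iterations: int | None = None,
    burn_in: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the whole study grid and emit the three study tables as CSV.

    table1: sire-variance posterior summaries at sigma_u2 = 0.05;
    table2: the same at sigma_u2 = 0.02; table3: Pearson correlations between
    true and estimated fixed/sire effects at sigma_u2 = 0.05.  At
    scale_factor < 1 all record/pedigree/chain sizes shrink proportionally and
    cells should be read for ordering and approximate magnitude.
    """
    summaries = []
    details = []
    for sigma in sigma_values:
        for ecp in ecp_levels:
            spec = ScenarioSpec(
                ecp_target=ecp,
                sigma_u2_true=sigma,
                g_weights=tuple(g_weights),
                n_replicates=n_replicates,
                scale_factor=scale_factor,
                n_iterations=n_iterations,
                burn_in=burn_in,
            )
            summary, detail = run_scenario(spec, master_seed)
            summaries.append(summary)
            details.append(detail)
    summary = pd.concat(summaries, ignore_index=True)
    detail = pd.concat(details, ignore_index=True)

    def variance_table(sigma: float) -> pd.DataFrame:
        sub = summary[np.isclose(summary["sigma_u2_true"], sigma)]
        return sub[
            [
                "ecp_target",
                "prior",
                "g_weight",
                "sigma_u2_mean",
                "sigma_u2_sd",
                "hpd_lower",
                "hpd_upper",
                "relative_bias",
            ]
        ].reset_index(drop=True)

    tables: dict[str, pd.DataFrame] = {}
    if any(np.isclose(sigma_values, 0.05)):
        tables["table1"] = variance_table(0.05)
        sub = summary[np.isclose(summary["sigma_u2_true"], 0.05)]
        tables["table3"] = sub[
            ["ecp_target", "prior", "g_weight", "pearson_fixed", "pearson_sire"]
        ].reset_index(drop=True)
    if any(np.isclose(sigma_values, 0.02)):
        tables["table2"] = variance_table(0.02)
    tables["detail"] = detail
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        (out / "run_config.json").write_text(
            json.dumps(
                dict(
                    master_seed=master_seed,
                    scale_factor=scale_factor,
                    sigma_values=list(sigma_values),
                    n_replicates=n_replicates,
                    ecp_levels=list(ecp_levels),
                    g_weights=list(g_weights),
                    dimensions=study_dimensions(scale_factor),
                ),
                indent=2,
            )
        )
    return tables
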