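"""Tab-delimited text interchange for records, pedigrees, effects and chains.

Conventions: files carry 1-based ids in the `*_id` columns; a sire-of-sire
of 0 or "NA" means unknown.  In memory everything is 0-based with -1 for
unknown parents.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .gibbs import GibbsResult
from .posterior import PosteriorSummary
from .simulator import UNKNOWN, Dataset, Pedigree, TrueEffects

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_pedigree",
    "read_pedigree",
    "write_true_effects",
    "read_true_effects",
    "write_chain",
    "write_summary_json",
]


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "record_id": np.arange(1, dataset.n_records + 1),
            "y": dataset.y.astype(int),
            "fixed_class": dataset.fixed_class + 1,
            "sire": dataset.sire + 1,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_dataset(
    path: str | Path, n_classes: int | None = None, n_sires: int | None = None
) -> Dataset:
    df = pd.read_csv(path, sep="\t")
    required = {"y", "fixed_class", "sire"}
    if not required.issubset(df.columns):
        raise ValueError(f"dataset file must have columns {sorted(required)}")
    cls = df["fixed_class"].to_numpy(dtype=np.int64) - 1
    sire = df["sire"].to_numpy(dtype=np.int64) - 1
    return Dataset(
        y=df["y"].to_numpy(dtype=np.int8),
        fixed_class=cls,
        sire=sire,
        n_classes=n_classes if n_classes is not None else int(cls.max()) + 1,
        n_sires=n_sires if n_sires is not None else int(sire.max()) + 1,
    )


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    sos = pedigree.sire_of_sire.copy() + 1
    sos[pedigree.sire_of_sire == UNKNOWN] = 0
    df = pd.DataFrame(
        {
            "sire_id": np.arange(1, pedigree.n_sires + 1),
            "sire_of_sire": sos,
            "generation": pedigree.generation,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    order = np.argsort(df["sire_id"].to_numpy())
    sos = df["sire_of_sire"].fillna(0).to_numpy(dtype=np.int64)[order] - 1
    sos[sos < 0] = UNKNOWN
    return Pedigree(
        sire_of_sire=sos, generation=df["generation"].to_numpy(dtype=np.int64)[order]
    )


def write_true_effects(effects: TrueEffects, path: str | Path) -> None:
    """Companion file for simulated data: long format (kind, index, value)."""
    rows = [
        *(("fixed", i + 1, v) for i, v in enumerate(effects.beta_true)),
        *(("sire", i + 1, v) for i, v in enumerate(effects.s_true)),
        ("sigma_u2", 0, effects.sigma_u2_true),
    ]
    pd.DataFrame(rows, columns=["kind", "index", "value"]).to_csv(
        path, sep="\t", index=False
    )


def read_true_effects(path: str | Path) -> TrueEffects:
    df = pd.read_csv(path, sep="\t")
    beta = df.loc[df["kind"] == "fixed"].sort_values("index")["value"].to_numpy()
    s = df.loc[df["kind"] == "sire"].sort_values("index")["value"].to_numpy()
    sigma = float(df.loc[df["kind"] == "sigma_u2", "value"].iloc[0])
    return TrueEffects(beta_true=beta, s_true=s, sigma_u2_true=sigma)


def write_chain(result: GibbsResult, path: str | Path) -> None:
    """Retained sire-variance draws, one row per post-burn-in iteration."""
    start = result.config.burn_in
    step = result.config.thinning
    pd.DataFrame(
        {
            "iteration": start + step * np.arange(result.n_retained),
            "sigma_u2": result.sigma_u2_draws,
        }
    ).to_csv(path, sep="\t", index=False)


def write_summary_json(
    summary: PosteriorSummary, path: str | Path, extra: dict | None = None
) -> None:
    payload = asdict(summary)
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))
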