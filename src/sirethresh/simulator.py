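"""Simulation of sire pedigrees and binary (liability-threshold) records.

The generative model is a probit-type threshold model on the liability scale:

    l_i = beta_{class(i)} + s_{sire(i)} + e_i,   e_i ~ N(0, 1)
    y_i = 1  if l_i > 0,  else 0

Fixed-class effects are drawn from a uniform distribution whose bounds are
calibrated so that a target fraction of classes exhibits the extreme case
problem (ECP): every record in the class falls in the same response category
(all 0 or all 1), leaving the class effect unidentified by the likelihood.

Sire transmitting abilities follow the pedigree: base sires are N(0, sigma_u2)
and a sire whose own sire (the daughters' grandsire) is known is
N(0.5 * s_parent, 0.75 * sigma_u2), so the marginal variance is sigma_u2 in
every generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "UNKNOWN",
    "Pedigree",
    "TrueEffects",
    "Dataset",
    "CalibrationError",
    "build_pedigree",
    "sample_transmitting_abilities",
    "simulate_dataset",
    "ecp_classes",
    "ecp_fraction",
    "calibrate_fixed_effect_bounds",
    "expected_ecp_fraction",
]

#: Sentinel for an unknown sire-of-sire.
UNKNOWN: int = -1

RngLike = Union[int, np.random.Generator, np.random.SeedSequence]


def as_rng(seed: RngLike) -> np.random.Generator:
    """Coerce an int seed / SeedSequence / Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class Pedigree:
    """A sire-only pedigree over overlapping generations.

    Attributes
    ----------
    sire_of_sire
        Parent index of each sire (``UNKNOWN`` = -1 for base sires).
    generation
        Generation number of each sire; base generation is 0.
    """

    sire_of_sire: np.ndarray
    generation: np.ndarray

    def __post_init__(self) -> None:
        sos = np.asarray(self.sire_of_sire, dtype=np.int64)
        gen = np.asarray(self.generation, dtype=np.int64)
        object.__setattr__(self, "sire_of_sire", sos)
        object.__setattr__(self, "generation", gen)
        if sos.shape != gen.shape or sos.ndim != 1:
            raise ValueError("sire_of_sire and generation must be 1-D and equal length")
        known = sos != UNKNOWN
        if np.any((sos < UNKNOWN) | (sos >= sos.size)):
            raise ValueError("parent indices out of range")
        if np.any(known & (gen[np.clip(sos, 0, None)] >= gen)):
            raise ValueError("a known parent must belong to a strictly earlier generation")
        if np.any((gen == 0) & known):
            raise ValueError("base-generation sires must have unknown parents")

    @property
    def n_sires(self) -> int:
        return self.sire_of_sire.size


@dataclass(frozen=True)
class TrueEffects:
    """True (generating) parameter values carried alongside a simulated dataset."""

    beta_true: np.ndarray
    s_true: np.ndarray
    sigma_u2_true: float


@dataclass(frozen=True)
class Dataset:
    """Binary records for a threshold sire model.

    ``liability_true`` is only present for simulated data; the invariant
    ``y_i = 1 <=> liability_true_i > 0`` then holds by construction.
    """

    y: np.ndarray
    fixed_class: np.ndarray
    sire: np.ndarray
    n_classes: int
    n_sires: int
    liability_true: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        y = np.ascontiguousarray(np.asarray(self.y, dtype=np.int8))
        cls = np.ascontiguousarray(np.asarray(self.fixed_class, dtype=np.int64))
        sire = np.ascontiguousarray(np.asarray(self.sire, dtype=np.int64))
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "fixed_class", cls)
        object.__setattr__(self, "sire", sire)
        if not (y.shape == cls.shape == sire.shape) or y.ndim != 1:
            raise ValueError("y, fixed_class and sire must be 1-D and equal length")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("responses must be 0/1")
        if cls.min(initial=0) < 0 or (cls.size and cls.max() >= self.n_classes):
            raise ValueError("fixed_class indices out of range")
        if sire.min(initial=0) < 0 or (sire.size and sire.max() >= self.n_sires):
            raise ValueError("sire indices out of range")
        if self.liability_true is not None:
            l = np.asarray(self.liability_true, dtype=np.float64)
            object.__setattr__(self, "liability_true", l)
            if l.shape != y.shape:
                raise ValueError("liability_true length mismatch")
            if np.any((l > 0) != (y == 1)):
                raise ValueError("liability sign inconsistent with responses")

    @property
    def n_records(self) -> int:
        return self.y.size


class CalibrationError(RuntimeError):
    """Raised when no uniform bounds achieve the requested ECP fraction."""


def build_pedigree(
    n_base: int, n_per_generation: int, n_generations: int, seed: RngLike
) -> Pedigree:
    """Build an overlapping-generation sire pedigree.

    The base generation holds ``n_base`` unrelated sires; each of the
    ``n_generations`` subsequent generations holds ``n_per_generation`` sires
    whose own sire is drawn uniformly from the pool of all earlier sires.
    """
    if n_base < 1:
        raise ValueError("n_base must be >= 1")
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    if n_per_generation < 0:
        raise ValueError("n_per_generation must be >= 0")
    rng = as_rng(seed)
    n_total = n_base + n_per_generation * n_generations
    sos = np.full(n_total, UNKNOWN, dtype=np.int64)
    gen = np.zeros(n_total, dtype=np.int64)
    start = n_base
    for g in range(1, n_generations + 1):
        stop = start + n_per_generation
        # pool of sires from all previous generations is exactly [0, start)
        sos[start:stop] = rng.integers(0, start, size=n_per_generation)
        gen[start:stop] = g
        start = stop
    return Pedigree(sire_of_sire=sos, generation=gen)


def sample_transmitting_abilities(
    pedigree: Pedigree, sigma_u2: float, seed: RngLike
) -> np.ndarray:
    """Sample sire transmitting abilities along the pedigree.

    Base sires ~ N(0, sigma_u2); a sire with known parent p ~
    N(0.5 * s_p, 0.75 * sigma_u2).  The recursion keeps the marginal variance
    equal to sigma_u2 in every generation.
    """
    if sigma_u2 <= 0:
        raise ValueError("sigma_u2 must be > 0")
    rng = as_rng(seed)
    s = np.empty(pedigree.n_sires, dtype=np.float64)
    z = rng.standard_normal(pedigree.n_sires)
    gens = np.unique(pedigree.generation)
    for g in gens:
        idx = np.flatnonzero(pedigree.generation == g)
        parents = pedigree.sire_of_sire[idx]
        known = parents != UNKNOWN
        mean = np.zeros(idx.size)
        var = np.full(idx.size, sigma_u2)
        if known.any():
            mean[known] = 0.5 * s[parents[known]]
            var[known] = 0.75 * sigma_u2
        s[idx] = mean + np.sqrt(var) * z[idx]
    return s


def simulate_dataset(
    pedigree: Pedigree,
    n_records: int,
    n_classes: int,
    bounds: tuple[float, float],
    sigma_u2: float,
    seed: RngLike,
) -> tuple[Dataset, TrueEffects]:
    """Simulate binary records under the liability threshold model.

    Records are assigned uniformly at random to fixed-effect classes and to
    sires (balanced in expectation, not exactly).  Class effects are drawn
    from Uniform(bounds); the liability is the sum of the class effect, the
    sire transmitting ability and a standard-normal residual, and the binary
    response is its sign indicator.
    """
    if n_records < n_classes:
        raise ValueError("need at least one record per class")
    lo, hi = float(bounds[0]), float(bounds[1])
    if not (np.isfinite(lo) and np.isfinite(hi)) or hi < lo:
        raise ValueError("bounds must be finite with lower <= upper")
    rng = as_rng(seed)
    beta_true = rng.uniform(lo, hi, size=n_classes)
    s_true = sample_transmitting_abilities(pedigree, sigma_u2, rng)
    cls = rng.integers(0, n_classes, size=n_records)
    # multinomial assignment can (very rarely) leave a class empty; redraw
    for _ in range(100):
        if np.bincount(cls, minlength=n_classes).min() > 0:
            break
        cls = rng.integers(0, n_classes, size=n_records)
    else:  # pragma: no cover - probability ~ exp(-records/classes)
        raise RuntimeError("could not assign at least one record to every class")
    sire = rng.integers(0, pedigree.n_sires, size=n_records)
    e = rng.standard_normal(n_records)
    liab = beta_true[cls] + s_true[sire] + e
    y = (liab > 0).astype(np.int8)
    ds = Dataset(
        y=y,
        fixed_class=cls,
        sire=sire,
        n_classes=n_classes,
        n_sires=pedigree.n_sires,
        liability_true=liab,
    )
    return ds, TrueEffects(beta_true=beta_true, s_true=s_true, sigma_u2_true=sigma_u2)


def ecp_classes(dataset: Dataset) -> np.ndarray:
    """Indices of extreme-case-problem classes (responses all 0 or all 1)."""
    n = np.bincount(dataset.fixed_class, minlength=dataset.n_classes)
    if n.min() == 0:
        raise ValueError("every fixed-effect class must have at least one record")
    ones = np.bincount(dataset.fixed_class, weights=dataset.y, minlength=dataset.n_classes)
    return np.flatnonzero((ones == 0) | (ones == n))


def ecp_fraction(dataset: Dataset) -> float:
    """Fraction of fixed-effect classes that are extreme-case problems."""
    return ecp_classes(dataset).size / dataset.n_classes


def _mean_ecp_fraction(
    pedigree: Pedigree,
    n_records: int,
    n_classes: int,
    bounds: tuple[float, float],
    sigma_u2: float,
    seed_seq: np.random.SeedSequence,
    n_datasets: int,
) -> tuple[float, float]:
    """Monte-Carlo mean (ECP fraction, incidence) over simulated datasets."""
    rng = np.random.default_rng(seed_seq)
    fracs = np.empty(n_datasets)
    incid = np.empty(n_datasets)
    lo, hi = bounds
    n_sires = pedigree.n_sires
    for r in range(n_datasets):
        beta = rng.uniform(lo, hi, size=n_classes)
        s = sample_transmitting_abilities(pedigree, sigma_u2, rng)
        cls = rng.integers(0, n_classes, size=n_records)
        sire = rng.integers(0, n_sires, size=n_records)
        liab = beta[cls] + s[sire] + rng.standard_normal(n_records)
        y = liab > 0
        n = np.bincount(cls, minlength=n_classes)
        ones = np.bincount(cls, weights=y, minlength=n_classes)
        nonempty = n > 0
        fracs[r] = np.mean((ones[nonempty] == 0) | (ones[nonempty] == n[nonempty]))
        incid[r] = y.mean()
    return float(fracs.mean()), float(incid.mean())


def expected_ecp_fraction(
    pedigree: Pedigree,
    n_records: int,
    n_classes: int,
    bounds: tuple[float, float],
    sigma_u2: float,
    seed: RngLike,
    n_datasets: int = 200,
) -> tuple[float, float]:
    """Monte-Carlo estimate of (mean ECP fraction, mean incidence) for given bounds."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return _mean_ecp_fraction(
        pedigree, n_records, n_classes, bounds, sigma_u2, ss, n_datasets
    )


def calibrate_fixed_effect_bounds(
    target_ecp: float,
    n_classes: int,
    records_per_class: int,
    sigma_u2: float,
    seed: RngLike,
    *,
    upper: float = 0.6,
    pedigree: Pedigree | None = None,
    n_eval: int = 120,
    n_confirm: int = 200,
    tolerance: float = 0.015,
) -> tuple[float, float]:
    """Calibrate Uniform(lower, upper) bounds for class effects to hit an ECP target.

    The upper bound is held fixed and the lower bound is pushed down the
    negative side of the real line by bisection: the further down it goes, the
    more classes have strongly negative effects, hence all-zero responses and
    more ECP.  Common random numbers across candidate bounds make the
    Monte-Carlo objective monotone, so bisection is deterministic given the
    seed.  A fresh confirmation run must land within ``tolerance`` (fraction)
    of the target or a :class:`CalibrationError` is raised.
    """
    if not 0.0 < target_ecp < 1.0:
        raise ValueError("target_ecp must lie strictly between 0 and 1")
    if n_classes < 1 or records_per_class < 1:
        raise ValueError("n_classes and records_per_class must be >= 1")
    base = (
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    eval_ss, confirm_ss, ped_ss = base.spawn(3)
    n_records = n_classes * records_per_class
    if pedigree is None:
        # default pedigree shaped like the study design: ~10 records per sire,
        # 10% base sires, three subsequent generations
        n_sires = max(4, n_records // 10)
        n_base = max(1, round(0.1 * n_sires))
        per_gen = max(1, round((n_sires - n_base) / 3))
        pedigree = build_pedigree(n_base, per_gen, 3, np.random.default_rng(ped_ss))

    def objective(lower: float) -> float:
        frac, _ = _mean_ecp_fraction(
            pedigree, n_records, n_classes, (lower, upper), sigma_u2, eval_ss, n_eval
        )
        return frac

    # bracket: ECP fraction decreases as the lower bound rises toward `upper`
    hi_lower = upper - 1e-3
    lo_lower = upper - 2.0
    f_lo = objective(lo_lower)
    while f_lo < target_ecp:
        lo_lower = upper - 2.0 * (upper - lo_lower)
        if upper - lo_lower > 64.0:
            raise CalibrationError(
                f"no lower bound above {lo_lower:.1f} reaches ECP target {target_ecp:.3f}"
            )
        f_lo = objective(lo_lower)
    if objective(hi_lower) > target_ecp:
        raise CalibrationError(
            f"ECP fraction at degenerate bounds already exceeds target {target_ecp:.3f}"
        )
    for _ in range(40):
        mid = 0.5 * (lo_lower + hi_lower)
        if objective(mid) >= target_ecp:
            lo_lower = mid
        else:
            hi_lower = mid
        if hi_lower - lo_lower < 1e-4:
            break
    lower = 0.5 * (lo_lower + hi_lower)
    achieved, _ = _mean_ecp_fraction(
        pedigree, n_records, n_classes, (lower, upper), sigma_u2, confirm_ss, n_confirm
    )
    if abs(achieved - target_ecp) > tolerance:
        raise CalibrationError(
            f"calibrated bounds ({lower:.4f}, {upper:.4f}) achieve ECP fraction "
            f"{achieved:.4f}, outside +/-{tolerance:.3f} of target {target_ecp:.3f}"
        )
    return float(lower), float(upper)
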