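"""Simulation of the seven missingness mechanisms.

Missing values in LC-MS feature tables arise from three canonical mechanisms:

* **MCAR** -- cells removed uniformly at random, independent of any value.
* **MAR** -- high abundance of one feature (the driver, X1) causes another
  feature (the target, X2) to be missing in the same sample: the top
  fraction of samples ranked by the driver lose their target value.
* **MNAR** -- a feature's own low values fall below the effective detection
  limit (left truncation): the smallest fraction of its observed values is
  removed.  Right truncation is available behind a flag but is not part of
  the benchmark defaults.

MAR and MNAR proceed in repeated events.  Each event draws its cut-off
fraction from chi-squared(1)/30 clipped to [0, 1] (mean ~3.3%, sd ~4.7%) and
masks that fraction of samples/values; events repeat until the requested
total proportion of cells is masked, with the final event trimmed so the
total count is exact.  Mixed mechanisms (MCAR_MAR, MCAR_MNAR, MAR_MNAR,
MCAR_MAR_MNAR) apply their components sequentially, each removing an equal
share of the total, each step operating on the output of the previous one.
Every masked cell is tagged with the event that produced it, so a mask's
provenance can be audited afterwards.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datasets import IntensityMatrix

__all__ = [
    "MECHANISMS",
    "MECHANISM_COMPONENTS",
    "MissingnessSpec",
    "MaskingEvent",
    "MaskedMatrix",
    "draw_cutoff_fraction",
    "simulate_mcar",
    "simulate_mar",
    "simulate_mnar",
    "simulate_mixed",
    "simulate_missingness",
]

logger = logging.getLogger(__name__)

MECHANISMS = (
    "MCAR",
    "MAR",
    "MNAR",
    "MCAR_MAR",
    "MCAR_MNAR",
    "MAR_MNAR",
    "MCAR_MAR_MNAR",
)

MECHANISM_COMPONENTS: dict[str, tuple[str, ...]] = {
    "MCAR": ("MCAR",),
    "MAR": ("MAR",),
    "MNAR": ("MNAR",),
    "MCAR_MAR": ("MCAR", "MAR"),
    "MCAR_MNAR": ("MCAR", "MNAR"),
    "MAR_MNAR": ("MAR", "MNAR"),
    "MCAR_MAR_MNAR": ("MCAR", "MAR", "MNAR"),
}

#: Paper rates; higher rates are allowed but logged (heavy masking tends to
#: turn any mechanism into an MNAR-looking pattern).
STANDARD_RATES = (0.05, 0.10, 0.20, 0.30)


class MechanismError(ValueError):
    """Raised for invalid mechanism parameters or degenerate inputs."""


@dataclass(frozen=True)
class MissingnessSpec:
    """Mechanism identifier + total missingness rate + truncation side."""

    mechanism: str
    rate: float
    truncation_side: str = "left"

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise MechanismError(
                f"unknown mechanism {self.mechanism!r}; expected one of {MECHANISMS}"
            )
        if not (0 < self.rate < 1):
            raise MechanismError(f"rate must lie in (0, 1), got {self.rate}")
        if self.truncation_side not in ("left", "right"):
            raise MechanismError(
                f"truncation_side must be 'left' or 'right', got {self.truncation_side!r}"
            )
        if self.rate > 0.30:
            logger.warning(
                "missingness rate %.2f exceeds 0.30; heavy masking tends to "
                "produce MNAR-like patterns regardless of mechanism",
                self.rate,
            )

    @property
    def components(self) -> tuple[str, ...]:
        return MECHANISM_COMPONENTS[self.mechanism]


@dataclass
class MaskingEvent:
    """One step of a mechanism simulation and the cells it masked."""

    step_mechanism: str
    driver_feature: str | None
    target_feature: str | None
    cutoff_fraction: float
    masked_cells: list[tuple[int, int]]


@dataclass
class MaskedMatrix:
    """An intensity matrix with simulated (or observed) missing entries.

    ``values`` holds NaN at masked cells; ``source`` is the complete matrix
    when the mask was simulated (None for data read from disk, where no
    ground truth exists).
    """

    values: np.ndarray
    mask: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    spec: MissingnessSpec | None = None
    events: list[MaskingEvent] = field(default_factory=list)
    source: IntensityMatrix | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise MechanismError("mask shape must equal matrix shape")
        if not np.array_equal(np.isnan(self.values), self.mask):
            raise MechanismError("NaN pattern of values must equal the mask")

    @property
    def n_missing(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def step_counts(self) -> dict[str, int]:
        """Number of masked cells attributed to each component mechanism."""
        counts: dict[str, int] = {}
        for ev in self.events:
            counts[ev.step_mechanism] = counts.get(ev.step_mechanism, 0) + len(
                ev.masked_cells
            )
        return counts


def draw_cutoff_fraction(rng: np.random.Generator) -> float:
    """One cut-off fraction: chi-squared(df=1) draw / 30, clipped to [0, 1].

    The unclipped distribution has mean 1/30 (~3.3%) and sd sqrt(2)/30
    (~4.7%); clipping at 1 changes the moments negligibly.
    """
    return float(min(rng.chisquare(1.0) / 30.0, 1.0))


def _target_count(rate: float, shape: tuple[int, int]) -> int:
    return int(round(rate * shape[0] * shape[1]))


def _mcar_fill(
    values: np.ndarray,
    mask: np.ndarray,
    n_new: int,
    rng: np.random.Generator,
    events: list[MaskingEvent],
) -> None:
    """Mask ``n_new`` cells uniformly without replacement among unmasked cells."""
    if n_new == 0:
        return
    flat_avail = np.flatnonzero(~mask.ravel())
    if n_new > flat_avail.size:
        raise MechanismError("not enough unmasked cells left for MCAR step")
    chosen = rng.choice(flat_avail, size=n_new, replace=False)
    rows, cols = np.unravel_index(chosen, mask.shape)
    mask[rows, cols] = True
    values[rows, cols] = np.nan
    events.append(
        MaskingEvent(
            step_mechanism="MCAR",
            driver_feature=None,
            target_feature=None,
            cutoff_fraction=float(n_new) / mask.size,
            masked_cells=list(zip(rows.tolist(), cols.tolist())),
        )
    )


def _mar_event(
    source: np.ndarray,
    mask: np.ndarray,
    driver: int,
    target: int,
    cutoff: float,
    n_cap: int,
) -> list[tuple[int, int]]:
    """Mask the target feature at the top-``cutoff`` samples by driver value.

    Driver ranks use the complete (source) values; cells of the target
    already masked are skipped.  At most ``n_cap`` cells are masked; when the
    event is trimmed, the highest-driver samples are kept so the top-fraction
    semantics survive trimming.
    """
    n_samples = source.shape[0]
    k = math.ceil(cutoff * n_samples)
    # descending driver order, deterministic tie-break on sample index
    order = np.argsort(-source[:, driver], kind="stable")
    avail = order[~mask[order, target]]
    take = avail[: min(k, n_cap, avail.size)]
    return [(int(i), target) for i in take]


def _mnar_event(
    source: np.ndarray,
    mask: np.ndarray,
    feature: int,
    cutoff: float,
    side: str,
    n_cap: int,
) -> list[tuple[int, int]]:
    """Truncate a feature's then-observed values below (left) or above (right)
    the cut point.  Trimming keeps the most extreme values.
    """
    obs = np.flatnonzero(~mask[:, feature])
    if obs.size == 0:
        return []
    k = math.ceil(cutoff * obs.size)
    order = obs[np.argsort(source[obs, feature], kind="stable")]  # ascending
    if side == "left":
        extreme_first = order
    else:
        extreme_first = order[::-1]
    take = extreme_first[: min(k, n_cap)]
    return [(int(i), feature) for i in take]


def _run_component(
    mech: str,
    source: np.ndarray,
    values: np.ndarray,
    mask: np.ndarray,
    n_target: int,
    rng: np.random.Generator,
    events: list[MaskingEvent],
    side: str,
    feature_ids: Sequence[str],
) -> None:
    """Mask exactly ``n_target`` additional cells with one component mechanism."""
    if n_target == 0:
        return
    if mech == "MCAR":
        _mcar_fill(values, mask, n_target, rng, events)
        return

    n_features = source.shape[1]
    if mech == "MAR" and n_features < 2:
        raise MechanismError("MAR requires at least 2 features")

    masked = 0
    attempts = 0
    while masked < n_target:
        attempts += 1
        if attempts > 200_000:
            raise MechanismError(
                f"{mech} simulation failed to reach the requested rate "
                f"({masked}/{n_target} cells masked)"
            )
        cutoff = draw_cutoff_fraction(rng)
        if mech == "MAR":
            driver, target = rng.choice(n_features, size=2, replace=False)
            cells = _mar_event(source, mask, int(driver), int(target), cutoff, n_target - masked)
            driver_id: str | None = feature_ids[int(driver)]
            target_id = feature_ids[int(target)]
        else:  # MNAR
            feat = int(rng.integers(n_features))
            cells = _mnar_event(source, mask, feat, cutoff, side, n_target - masked)
            driver_id = feature_ids[feat]
            target_id = feature_ids[feat]
        if not cells:
            continue
        rows = [c[0] for c in cells]
        cols = [c[1] for c in cells]
        mask[rows, cols] = True
        values[rows, cols] = np.nan
        masked += len(cells)
        events.append(
            MaskingEvent(
                step_mechanism=mech,
                driver_feature=driver_id,
                target_feature=target_id,
                cutoff_fraction=cutoff,
                masked_cells=cells,
            )
        )


def _simulate(
    matrix: IntensityMatrix,
    components: Sequence[str],
    rate: float,
    rng: np.random.Generator,
    side: str,
    spec: MissingnessSpec | None,
) -> MaskedMatrix:
    if len(set(components)) != len(components):
        raise MechanismError(f"duplicate component mechanisms in {components}")
    for mech in components:
        if mech not in ("MCAR", "MAR", "MNAR"):
            raise MechanismError(f"unknown component mechanism {mech!r}")
    if not (0 <= rate < 1):
        raise MechanismError(f"rate must lie in [0, 1), got {rate}")

    source = matrix.values
    values = source.copy()
    mask = np.zeros(source.shape, dtype=bool)
    events: list[MaskingEvent] = []

    total = _target_count(rate, source.shape)
    k = len(components)
    # equal split via cumulative rounding: quotas sum to `total` exactly
    cum = [round(total * (i + 1) / k) for i in range(k)]
    quotas = [cum[0]] + [cum[i] - cum[i - 1] for i in range(1, k)]
    for mech, quota in zip(components, quotas):
        _run_component(
            mech, source, values, mask, quota, rng, events, side, matrix.feature_ids
        )

    assert int(mask.sum()) == total
    return MaskedMatrix(
        values=values,
        mask=mask,
        sample_ids=list(matrix.sample_ids),
        feature_ids=list(matrix.feature_ids),
        spec=spec,
        events=events,
        source=matrix,
    )


def simulate_mcar(
    matrix: IntensityMatrix, rate: float, rng: np.random.Generator | int
) -> MaskedMatrix:
    """Mask round(rate * cells) cells uniformly at random."""
    rng = np.random.default_rng(rng)
    spec = MissingnessSpec("MCAR", rate) if 0 < rate < 1 else None
    return _simulate(matrix, ("MCAR",), rate, rng, "left", spec)


def simulate_mar(
    matrix: IntensityMatrix, rate: float, rng: np.random.Generator | int
) -> MaskedMatrix:
    """Abundance-driven missingness: high driver values mask a second feature."""
    rng = np.random.default_rng(rng)
    spec = MissingnessSpec("MAR", rate) if 0 < rate < 1 else None
    return _simulate(matrix, ("MAR",), rate, rng, "left", spec)


def simulate_mnar(
    matrix: IntensityMatrix,
    rate: float,
    rng: np.random.Generator | int,
    side: str = "left",
) -> MaskedMatrix:
    """Detection-limit truncation of features' own values (default left)."""
    if side not in ("left", "right"):
        raise MechanismError(f"truncation side must be 'left' or 'right', got {side!r}")
    rng = np.random.default_rng(rng)
    spec = MissingnessSpec("MNAR", rate, side) if 0 < rate < 1 else None
    return _simulate(matrix, ("MNAR",), rate, rng, side, spec)


def simulate_mixed(
    matrix: IntensityMatrix,
    components: Sequence[str],
    rate: float,
    rng: np.random.Generator | int,
    side: str = "left",
) -> MaskedMatrix:
    """Apply 2-3 component mechanisms sequentially, equal share of cells each."""
    if not (2 <= len(components) <= 3):
        raise MechanismError("mixed mechanisms take 2 or 3 components")
    rng = np.random.default_rng(rng)
    name = "_".join(components)
    spec = (
        MissingnessSpec(name, rate, side)
        if name in MECHANISMS and 0 < rate < 1
        else None
    )
    return _simulate(matrix, tuple(components), rate, rng, side, spec)


def simulate_missingness(
    matrix: IntensityMatrix, spec: MissingnessSpec, seed: int | np.random.Generator
) -> MaskedMatrix:
    """Dispatch to the single-mechanism or mixed simulator; seeded."""
    rng = np.random.default_rng(seed)
    masked = _simulate(
        matrix, spec.components, spec.rate, rng, spec.truncation_side, spec
    )
    return masked
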