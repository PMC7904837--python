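"""Trajectory ensembles, discretization into a shared emission alphabet, and text I/O.

A :class:`TrajectoryEnsemble` holds the continuous single-cell response matrix for one
stimulus condition (rows = cells, columns = timepoints).  Before any model fitting the
continuous values are binned into a common discrete alphabet; one
:class:`DiscretizationScheme` is fitted on data pooled across *all* conditions so that
every per-condition model shares the same emission symbols and their likelihoods are
comparable.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


class TrajectoryDataError(Exception):
    """Base class for trajectory-data errors."""


class EnsembleFileMissingError(TrajectoryDataError):
    """A manifest entry points at a file that does not exist."""


class RaggedMatrixError(TrajectoryDataError):
    """A trajectory matrix has rows of unequal length or missing cells."""


class NonNumericValueError(TrajectoryDataError):
    """A trajectory matrix contains a cell that does not parse as a number."""


class DuplicateLabelError(TrajectoryDataError):
    """Two manifest entries carry the same condition label."""


class DegenerateDataWarning(UserWarning):
    """Emitted when discretization falls back due to constant-valued data."""


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """Continuous cells x timepoints signal matrix for one stimulus condition.

    Parameters
    ----------
    condition_label : str
        Name of the stimulus condition (e.g. ligand + concentration).
    values : ndarray, shape (n_cells, n_timepoints)
        Signal intensity in arbitrary units; must be finite.
    time_step : float
        Minutes per column.
    """

    condition_label: str
    values: np.ndarray
    time_step: float = 1.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise TrajectoryDataError("trajectory matrix must be 2-dimensional")
        if vals.shape[0] < 1 or vals.shape[1] < 2:
            raise TrajectoryDataError(
                "ensemble needs >= 1 cell and >= 2 timepoints, got shape "
                f"{vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise TrajectoryDataError("trajectory matrix contains non-finite entries")
        if not self.time_step > 0:
            raise TrajectoryDataError("time_step must be positive")
        object.__setattr__(self, "values", vals)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class DiscretizationScheme:
    """Bin edges mapping continuous signal values to emission symbols.

    ``bin_edges`` has length ``n_symbols + 1`` and is strictly increasing.  Bins are
    half-open ``[a, b)`` with the final bin closed on the right; values outside the
    fitted range clamp to the first/last bin (the outer edges are conceptually
    infinite), so a scheme fitted on one data split can always encode the other.
    """

    bin_edges: np.ndarray
    strategy: str

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        if edges.ndim != 1 or edges.size < 3:
            raise TrajectoryDataError("need at least 3 edges (2 symbols)")
        if not np.all(np.diff(edges) > 0):
            raise TrajectoryDataError("bin edges must be strictly increasing")
        if self.strategy not in ("equal_width", "quantile"):
            raise TrajectoryDataError(f"unknown binning strategy {self.strategy!r}")
        object.__setattr__(self, "bin_edges", edges)

    @property
    def n_symbols(self) -> int:
        return self.bin_edges.size - 1

    @property
    def scheme_id(self) -> str:
        h = hashlib.sha1()
        h.update(self.strategy.encode())
        h.update(self.bin_edges.tobytes())
        return h.hexdigest()[:12]


@dataclass(frozen=True)
class DiscreteEnsemble:
    """Integer state sequences over a shared emission alphabet.

    ``scheme_id`` ties the ensemble to the :class:`DiscretizationScheme` (or synthetic
    generator) that produced it; cross-condition computations assert that all ensembles
    share one id, i.e. one alphabet.
    """

    condition_label: str
    states: np.ndarray
    n_symbols: int
    scheme_id: str | None = None

    def __post_init__(self) -> None:
        states = np.asarray(self.states)
        if states.ndim != 2:
            raise TrajectoryDataError("state matrix must be 2-dimensional")
        if not np.issubdtype(states.dtype, np.integer):
            if not np.all(states == states.astype(int)):
                raise TrajectoryDataError("state matrix must be integer-valued")
            states = states.astype(np.int64)
        if self.n_symbols < 2:
            raise TrajectoryDataError("alphabet needs >= 2 symbols")
        if states.size and (states.min() < 0 or states.max() >= self.n_symbols):
            raise TrajectoryDataError(
                f"states must lie in [0, {self.n_symbols}); "
                f"found range [{states.min()}, {states.max()}]"
            )
        object.__setattr__(self, "states", states)

    @property
    def n_cells(self) -> int:
        return self.states.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.states.shape[1]


@dataclass(frozen=True)
class ConditionManifest:
    """Ordered (condition_label, file path) index over the M stimulus conditions."""

    entries: tuple[tuple[str, str], ...]
    time_step: float = 1.0

    def __post_init__(self) -> None:
        entries = tuple((str(lbl), str(p)) for lbl, p in self.entries)
        labels = [lbl for lbl, _ in entries]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise DuplicateLabelError(f"duplicate condition labels: {sorted(dupes)}")
        if len(entries) < 1:
            raise TrajectoryDataError("manifest needs at least one entry")
        object.__setattr__(self, "entries", entries)

    @property
    def n_conditions(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> list[str]:
        return [lbl for lbl, _ in self.entries]


def load_manifest(path: str | Path) -> ConditionManifest:
    """Read a manifest from its YAML key-value file."""
    path = Path(path)
    if not path.exists():
        raise EnsembleFileMissingError(f"manifest not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = tuple((e["label"], e["path"]) for e in doc["conditions"])
    return ConditionManifest(entries=entries, time_step=float(doc.get("time_step", 1.0)))


def save_manifest(manifest: ConditionManifest, path: str | Path) -> None:
    doc = {
        "time_step": float(manifest.time_step),
        "conditions": [{"label": l, "path": p} for l, p in manifest.entries],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _read_matrix(path: Path) -> np.ndarray:
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
    try:
        df = pd.read_csv(path, sep=sep, header=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise RaggedMatrixError(f"{path}: {exc}") from exc
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise NonNumericValueError(f"{path}: {exc}") from exc
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise RaggedMatrixError(f"{path}: missing cells (ragged rows?)")
    return values


def read_ensembles(
    manifest: ConditionManifest | str | Path, base_dir: str | Path | None = None
) -> list[TrajectoryEnsemble]:
    """Load one :class:`TrajectoryEnsemble` per manifest entry, in manifest order.

    File paths are resolved relative to ``base_dir`` (defaults to the manifest's own
    directory when ``manifest`` is a path, else the working directory).
    """
    if not isinstance(manifest, ConditionManifest):
        manifest_path = Path(manifest)
        if base_dir is None:
            base_dir = manifest_path.parent
        manifest = load_manifest(manifest_path)
    base = Path(base_dir) if base_dir is not None else Path(".")
    ensembles = []
    for label, relpath in manifest.entries:
        path = base / relpath
        if not path.exists():
            raise EnsembleFileMissingError(f"condition {label!r}: file not found {path}")
        values = _read_matrix(path)
        ensembles.append(
            TrajectoryEnsemble(condition_label=label, values=values,
                               time_step=manifest.time_step)
        )
    return ensembles


def write_ensembles(
    ensembles: list[TrajectoryEnsemble], directory: str | Path,
    manifest_name: str = "manifest.yaml",
) -> ConditionManifest:
    """Write each ensemble as a CSV (header row = timepoint minutes) plus a manifest.

    Round-trip contract: ``read_ensembles(write_ensembles(x))`` reproduces values and
    labels exactly (floats are written with full repr precision).
    """
    if not ensembles:
        raise TrajectoryDataError("no ensembles to write")
    labels = [e.condition_label for e in ensembles]
    if len(set(labels)) != len(labels):
        raise DuplicateLabelError(f"duplicate condition labels: {labels}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    time_step = ensembles[0].time_step
    entries = []
    for ens in ensembles:
        fname = f"{ens.condition_label}.csv"
        header = [f"t{j * ens.time_step:g}" for j in range(ens.n_timepoints)]
        df = pd.DataFrame(ens.values, columns=header)
        df.to_csv(directory / fname, index=False, float_format="%.17g")
        entries.append((ens.condition_label, fname))
    manifest = ConditionManifest(entries=tuple(entries), time_step=time_step)
    save_manifest(manifest, directory / manifest_name)
    return manifest


def fit_discretization(
    ensembles: list[TrajectoryEnsemble], n_symbols: int, strategy: str = "quantile"
) -> DiscretizationScheme:
    """Fit one binning scheme on values pooled across all conditions.

    Pooling is essential: all per-condition models must share one emission alphabet for
    cross-condition likelihoods (and hence any mutual-information estimate) to be well
    defined.  ``quantile`` (default) gives near-equal bin occupancy, which conditions
    the transition-count matrices well; ``equal_width`` is available for data whose raw
    scale is meaningful.  Constant-valued data fall back to a unit-width window with a
    :class:`DegenerateDataWarning`.
    """
    if n_symbols < 2:
        raise TrajectoryDataError("n_symbols must be >= 2")
    if not ensembles:
        raise TrajectoryDataError("no ensembles to fit on")
    pooled = np.concatenate([e.values.ravel() for e in ensembles])
    lo, hi = float(pooled.min()), float(pooled.max())
    if lo == hi:
        warnings.warn(
            "all pooled values identical; falling back to equal-width bins on "
            f"[{lo - 0.5}, {lo + 0.5}]", DegenerateDataWarning)
        edges = np.linspace(lo - 0.5, lo + 0.5, n_symbols + 1)
        return DiscretizationScheme(bin_edges=edges, strategy="equal_width")
    if strategy == "equal_width":
        edges = np.linspace(lo, hi, n_symbols + 1)
    elif strategy == "quantile":
        edges = np.quantile(pooled, np.linspace(0.0, 1.0, n_symbols + 1))
        if not np.all(np.diff(edges) > 0):
            # heavy ties (e.g. an atom at the detection floor) collapse quantiles;
            # fall back to equal width rather than silently changing the alphabet
            warnings.warn(
                "quantile edges are not distinct (tied values dominate); "
                "falling back to equal-width bins", DegenerateDataWarning)
            edges = np.linspace(lo, hi, n_symbols + 1)
            return DiscretizationScheme(bin_edges=edges, strategy="equal_width")
    else:
        raise TrajectoryDataError(f"unknown binning strategy {strategy!r}")
    return DiscretizationScheme(bin_edges=edges, strategy=strategy)


def discretize(ensemble: TrajectoryEnsemble, scheme: DiscretizationScheme) -> DiscreteEnsemble:
    """Map a continuous ensemble onto the scheme's symbols.

    Deterministic and monotone: bins are half-open ``[a, b)`` (ties at an interior edge
    go to the upper bin), the last bin is closed, and out-of-range values clamp to the
    boundary bins.
    """
    inner = scheme.bin_edges[1:-1]
    states = np.searchsorted(inner, ensemble.values, side="right")
    return DiscreteEnsemble(
        condition_label=ensemble.condition_label,
        states=states.astype(np.int64),
        n_symbols=scheme.n_symbols,
        scheme_id=scheme.scheme_id,
    )


def discretize_all(
    ensembles: list[TrajectoryEnsemble], scheme: DiscretizationScheme
) -> list[DiscreteEnsemble]:
    return [discretize(e, scheme) for e in ensembles]


def subset_rows(ensemble, rows: np.ndarray):
    """Return a copy of a (continuous or discrete) ensemble restricted to ``rows``."""
    rows = np.asarray(rows)
    if isinstance(ensemble, DiscreteEnsemble):
        return replace(ensemble, states=ensemble.states[rows])
    return replace(ensemble, values=ensemble.values[rows])
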