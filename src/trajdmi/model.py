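"""High-level Model/Results interface for the dMI workflow.

:class:`DynamicalMI` is built from one trajectory ensemble per stimulus condition
(continuous or already discretized); :meth:`DynamicalMI.fit` discretizes on the pooled
data, trains one per-condition generative model, scores every trajectory under every
condition's model, and maximizes the dMI at each cumulative timepoint.  The returned
:class:`DMIResults` carries the fitted models, the curve, the optimal stimulus weights
and a text ``summary()``.

Example
-------
>>> from trajdmi import DynamicalMI, ToySpec, generate_toy_hmm_ensembles
>>> ensembles, truth = generate_toy_hmm_ensembles(ToySpec(n_conditions=2, seed=7))
>>> res = DynamicalMI(ensembles, family="hmm").fit(seed=7)
>>> round(res.max_dmi, 2)
1.0
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import (
    DiscreteEnsemble,
    TrajectoryEnsemble,
    discretize_all,
    fit_discretization,
    read_ensembles,
)
from .dmi import DMICurve, DMIError, dmi_curve_from_scores, score_conditions
from .models import ModelConfig


class DynamicalMI:
    """Dynamical mutual information between stimulus identity and response trajectories.

    Parameters
    ----------
    ensembles : list of TrajectoryEnsemble or DiscreteEnsemble
        One ensemble per stimulus condition (M >= 2).  Continuous ensembles are
        discretized at fit time with one scheme pooled across all conditions.
    family : {"hmm", "markov"}
        Per-condition model family.
    n_symbols : int
        Emission alphabet size used when discretizing continuous input.
    n_hidden : int, optional
        Hidden-state count for the HMM family; defaults to ``2 * n_symbols``
        (the 2:1 hidden:emission ratio).
    binning : {"quantile", "equal_width"}
        Discretization strategy for continuous input.
    """

    def __init__(
        self,
        ensembles,
        family: str = "hmm",
        n_symbols: int = 8,
        n_hidden: int | None = None,
        binning: str = "quantile",
        config: ModelConfig | None = None,
    ):
        if len(ensembles) < 2:
            raise DMIError("need M >= 2 stimulus conditions")
        kinds = {isinstance(e, DiscreteEnsemble) for e in ensembles}
        if len(kinds) != 1:
            raise DMIError("cannot mix continuous and discrete ensembles")
        self.ensembles = list(ensembles)
        self.is_discrete = isinstance(ensembles[0], DiscreteEnsemble)
        self.n_symbols = ensembles[0].n_symbols if self.is_discrete else n_symbols
        self.binning = binning
        self.config = config or ModelConfig(family=family, n_hidden=n_hidden)
        if config is None:
            self.config.family = family
            self.config.n_hidden = n_hidden

    @classmethod
    def from_manifest(cls, manifest_path, **kwargs) -> "DynamicalMI":
        """Build the model from a condition manifest on disk."""
        return cls(read_ensembles(manifest_path), **kwargs)

    def fit(self, seed: int = 0, tol: float = 1e-6) -> "DMIResults":
        """Discretize, fit per-condition models, score, and maximize the dMI."""
        if self.is_discrete:
            discrete = self.ensembles
            scheme = None
        else:
            scheme = fit_discretization(self.ensembles, self.n_symbols, self.binning)
            discrete = discretize_all(self.ensembles, scheme)
        rng = np.random.default_rng(seed)
        models = [self.config.fit(d, seed=int(rng.integers(2**31))) for d in discrete]
        scores = score_conditions(models, discrete)
        curve = dmi_curve_from_scores(scores, tol=tol)
        return DMIResults(
            model=self, scheme=scheme, discrete=discrete, fitted_models=models,
            scores=scores, curve=curve, seed=seed,
        )


@dataclass
class DMIResults:
    """Results of a :class:`DynamicalMI` fit."""

    model: DynamicalMI
    scheme: object
    discrete: list
    fitted_models: list
    scores: object
    curve: DMICurve
    seed: int

    @property
    def labels(self) -> tuple[str, ...]:
        return self.curve.labels

    @property
    def max_dmi(self) -> float:
        """Maximum dMI (bits) at the final timepoint."""
        return self.curve.final_max_dmi

    @property
    def optimal_weights(self) -> np.ndarray:
        """Optimal stimulus weights at the final timepoint."""
        return self.curve.optimal_q[-1]

    def summary(self) -> str:
        M = len(self.labels)
        lines = [
            "Dynamical mutual information".center(58),
            "=" * 58,
            f"Conditions (M):        {M}",
            f"Model family:          {self.model.config.family}",
            f"Emission symbols:      {self.model.n_symbols}",
        ]
        if self.model.config.family == "hmm":
            lines.append(
                f"Hidden states:         {self.model.config.resolve_hidden(self.model.n_symbols)}"
            )
        lines += [
            f"Timepoints (N):        {self.curve.timepoints[-1]}",
            f"Seed:                  {self.seed}",
            "-" * 58,
            f"Max dMI @ final n:     {self.max_dmi:.4f} bits "
            f"(ceiling log2 M = {np.log2(M):.4f})",
            f"Uniform-q dMI:         {self.curve.uniform_dmi[-1]:.4f} bits",
            "Optimal stimulus weights @ final n:",
        ]
        for lbl, w in zip(self.labels, self.optimal_weights):
            lines.append(f"    {lbl:<24s} {w:8.4f}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the maximum-dMI curve (and the uniform-weight curve) vs timepoint."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        ax.plot(self.curve.timepoints, self.curve.max_dmi, label="maximum dMI")
        ax.plot(
            self.curve.timepoints, self.curve.uniform_dmi,
            linestyle="--", label="uniform-q dMI",
        )
        ax.axhline(np.log2(len(self.labels)), color="grey", lw=0.8, ls=":",
                   label=r"$\log_2 M$")
        ax.set_xlabel("timepoint n")
        ax.set_ylabel("mutual information (bits)")
        ax.legend()
        return ax

    def save_curve(self, path) -> None:
        self.curve.save(path, metadata={
            "seed": self.seed,
            "family": self.model.config.family,
            "n_symbols": int(self.model.n_symbols),
            "n_hidden": int(self.model.config.resolve_hidden(self.model.n_symbols))
            if self.model.config.family == "hmm" else None,
            "labels": list(self.labels),
        })
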