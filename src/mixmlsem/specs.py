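"""Model specifications shared across the estimation steps.

A :class:`MeasurementSpec` describes how observed items map onto latent
factors (one measurement block per factor) and which measurement parameters
carry group-level random effects.  A :class:`StructuralSpec` describes the
directed regression pattern among the factors.  :class:`MCMCSettings`
collects the sampler controls for the multilevel CFA of Step 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

__all__ = ["MeasurementSpec", "StructuralSpec", "MCMCSettings"]


@dataclass
class MeasurementSpec:
    """Factor -> item mapping plus the invariance pattern.

    Parameters
    ----------
    factor_blocks : dict[str, list[str]]
        Ordered item columns per factor; each item belongs to exactly one
        factor (single-factor measurement blocks).
    marker_items : dict[str, str]
        Per factor, the item whose loading is fixed to 1 in every group so
        that a one-unit change of the factor has the same meaning in all
        groups.  Defaults to the first item of each block.
    random_loading_items : dict[str, list[str]]
        Items whose loadings vary across groups (normal random effects).
    random_uniqueness_items : dict[str, list[str]]
        Items whose unique variances vary across groups (log-normal random
        effects).
    residual_cov_pairs : list[tuple[str, str]]
        Item pairs with a free residual covariance (2x2 joint residual
        block); both members must have invariant unique variances.
    random_factor_variance : dict[str, bool]
        Whether the factor variance is group-specific (log-normal random
        effect).  Defaults to True for every factor.
    """

    factor_blocks: dict
    marker_items: dict = field(default_factory=dict)
    random_loading_items: dict = field(default_factory=dict)
    random_uniqueness_items: dict = field(default_factory=dict)
    residual_cov_pairs: list = field(default_factory=list)
    random_factor_variance: dict = field(default_factory=dict)

    def __post_init__(self):
        seen = {}
        for f, items in self.factor_blocks.items():
            if not items:
                raise ValueError(f"factor {f!r} has no items")
            for it in items:
                if it in seen:
                    raise ValueError(
                        f"item {it!r} appears in blocks {seen[it]!r} and {f!r}; "
                        "each item must belong to exactly one factor"
                    )
                seen[it] = f
        for f in self.factor_blocks:
            self.marker_items.setdefault(f, self.factor_blocks[f][0])
            self.random_loading_items.setdefault(f, [])
            self.random_uniqueness_items.setdefault(f, [])
            self.random_factor_variance.setdefault(f, True)
        for f, marker in self.marker_items.items():
            if marker not in self.factor_blocks[f]:
                raise ValueError(f"marker {marker!r} not an item of factor {f!r}")
            if marker in self.random_loading_items[f]:
                raise ValueError(f"marker {marker!r} cannot have a random loading")
        flat = seen
        for a, b in self.residual_cov_pairs:
            if a not in flat or b not in flat:
                raise ValueError(f"residual covariance pair ({a!r}, {b!r}) has unknown items")

    @property
    def factors(self) -> list:
        return list(self.factor_blocks)

    @property
    def n_factors(self) -> int:
        return len(self.factor_blocks)

    def items_of(self, factor) -> list:
        return list(self.factor_blocks[factor])

    @classmethod
    def simulation_default(cls) -> "MeasurementSpec":
        """The 4-factor, 5-items-per-factor design of the simulation studies.

        Items ``y1..y20``; the first item of each factor is the marker and
        the second and third items carry random loadings and random unique
        variances.
        """
        blocks, rload, runiq = {}, {}, {}
        for q in range(4):
            f = f"F{q + 1}"
            items = [f"y{5 * q + j + 1}" for j in range(5)]
            blocks[f] = items
            rload[f] = items[1:3]
            runiq[f] = items[1:3]
        return cls(factor_blocks=blocks, random_loading_items=rload,
                   random_uniqueness_items=runiq)


@dataclass
class StructuralSpec:
    """Directed (recursive) regression pattern among the factors."""

    factor_order: list
    free_paths: list  # list of (source, target) pairs
    exogenous: list

    def __post_init__(self):
        idx = {f: i for i, f in enumerate(self.factor_order)}
        for s, t in self.free_paths:
            if s not in idx or t not in idx:
                raise ValueError(f"path ({s!r}, {t!r}) uses unknown factors")
            if t in self.exogenous:
                raise ValueError(f"exogenous factor {t!r} cannot receive a path")
        # recursiveness: require a topological order; factor_order must be one
        for s, t in self.free_paths:
            if idx[s] >= idx[t]:
                raise ValueError(
                    "free_paths must respect factor_order (recursive model); "
                    f"({s!r} -> {t!r}) violates it"
                )

    @property
    def n_factors(self) -> int:
        return len(self.factor_order)

    @property
    def endogenous(self) -> list:
        return [f for f in self.factor_order if f not in self.exogenous]

    def path_indices(self) -> list:
        """Free B cells as (row, col) positions: B[t, s] regresses t on s."""
        idx = {f: i for i, f in enumerate(self.factor_order)}
        return [(idx[t], idx[s]) for s, t in self.free_paths]

    @classmethod
    def four_factor_default(cls) -> "StructuralSpec":
        """F1 and F2 exogenous; F3 on F1 and F2; F4 on F1 and F3.

        The canonical coefficient labels are beta1: F1->F4, beta2: F1->F3,
        beta3: F2->F3, beta4: F3->F4.
        """
        return cls(
            factor_order=["F1", "F2", "F3", "F4"],
            free_paths=[("F1", "F3"), ("F2", "F3"), ("F1", "F4"), ("F3", "F4")],
            exogenous=["F1", "F2"],
        )


# canonical label -> (source, target) for the four-factor simulation model
BETA_PATHS = {
    "beta1": ("F1", "F4"),
    "beta2": ("F1", "F3"),
    "beta3": ("F2", "F3"),
    "beta4": ("F3", "F4"),
}


@dataclass
class MCMCSettings:
    """Controls for the Gibbs sampler of the multilevel CFA.

    ``prior_mean_sd`` is the SD of the normal priors on loading means and
    log-scale variance means; ``prior_scale_hc`` the scale of the
    half-Cauchy priors on random-effect SDs; ``prior_ig_shape/rate`` the
    inverse-gamma prior on invariant variances.
    """

    chains: int = 2
    iterations: int = 4000
    burn_in: int = 2000
    thinning: int = 1
    seed: int = 0
    prior_mean_sd: float = 10.0
    prior_scale_hc: float = 1.0
    prior_ig_shape: float = 0.5
    prior_ig_rate: float = 0.5
    rhat_threshold: float = 1.05

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)
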