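"""Module-level evolutionary rate comparisons (head vs. trunk style tests).

Two-step design: (1) do named landmark modules evolve at different rates
across the whole tree (r_mult, max/min of per-module rates)? (2) within each
module, do the two clades differ in rate (delegated to the clade test on the
module's columns)?
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping

import numpy as np

from .landmarks import ShapeMatrix, subset_landmarks
from .rates import (
    RateTestResult,
    _covariance_roots,
    _max_min_ratio,
    _pooled_rate_matrix,
    rate_ratio_test,
)
from .trees import Chronogram, phylo_covariance

__all__ = [
    "ModulePartition",
    "ModularityResult",
    "DEFAULT_PARTITION",
    "module_rates",
    "modularity_rate_test",
    "within_module_clade_test",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModulePartition:
    """Named, disjoint 1-based landmark index sets.

    Landmarks outside every module are permitted (and ignored with a logged
    note) so alternative schemes can reuse the machinery.
    """

    modules: dict[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        clean: dict[str, tuple[int, ...]] = {}
        seen: set[int] = set()
        for name, idx in self.modules.items():
            idx = tuple(sorted(set(int(i) for i in idx)))
            if not idx:
                raise ValueError(f"module {name!r} is empty")
            if any(i < 1 for i in idx):
                raise ValueError(f"module {name!r} has non-positive landmark indices")
            overlap = seen.intersection(idx)
            if overlap:
                raise ValueError(f"module {name!r} overlaps others at {sorted(overlap)}")
            seen.update(idx)
            clean[name] = idx
        object.__setattr__(self, "modules", clean)

    def validate_for(self, k: int) -> None:
        for name, idx in self.modules.items():
            if idx[-1] > k:
                raise IndexError(
                    f"module {name!r} references landmark {idx[-1]} but k={k}"
                )
        covered = set().union(*self.modules.values())
        leftover = set(range(1, k + 1)) - covered
        if leftover:
            logger.info("landmarks outside all modules (ignored): %s", sorted(leftover))

    def columns(self, name: str) -> list[int]:
        """0-based trait-column indices (x/y pairs) of a module."""
        return [c for i in self.modules[name] for c in (2 * (i - 1), 2 * (i - 1) + 1)]


#: the default anatomical scheme for an 18-landmark fish body:
#: head = trophic region, trunk = locomotor region
DEFAULT_PARTITION = ModulePartition(
    {"head": tuple(range(1, 9)) + tuple(range(15, 19)), "trunk": tuple(range(9, 15))}
)


@dataclass(frozen=True)
class ModularityResult:
    sigma2_by_module: dict[str, float]
    r_mult: float
    module_numerator: str
    module_denominator: str
    p_value: float
    nsim: int
    seed: int | None

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), sort_keys=True, **kwargs)

    def to_csv_row(self) -> dict:
        row = {f"sigma2_{m}": v for m, v in sorted(self.sigma2_by_module.items())}
        row.update(
            r_mult=self.r_mult,
            module_numerator=self.module_numerator,
            module_denominator=self.module_denominator,
            p_value=self.p_value,
            nsim=self.nsim,
            seed=self.seed,
        )
        return row


def module_rates(
    Yt: np.ndarray, partition: ModulePartition, k: int | None = None
) -> dict[str, float]:
    """Per-module per-trait rates from whitened residuals.

    For module m with p_m = 2 * |landmarks_m| trait columns,
    sigma2_m = sum_i ||Yt[i, cols_m]||^2 / (n * p_m).
    """
    Yt = np.asarray(Yt, dtype=float)
    n, p = Yt.shape
    if p % 2 != 0:
        raise ValueError("whitened matrix must have x/y column pairs")
    partition.validate_for(k if k is not None else p // 2)
    rates: dict[str, float] = {}
    for name in partition.modules:
        cols = partition.columns(name)
        if max(cols) >= p:
            raise IndexError(f"module {name!r} exceeds trait layout")
        rates[name] = float((Yt[:, cols] ** 2).sum() / (n * len(cols)))
    return rates


def modularity_rate_test(
    Y: ShapeMatrix,
    tree: Chronogram,
    partition: ModulePartition = DEFAULT_PARTITION,
    nsim: int = 9999,
    seed: int | None = None,
    isotropic_null: bool = False,
) -> ModularityResult:
    """Do the modules evolve at different rates tree-wide?

    Observed r_mult = max/min of per-module whitened rates. The null rescales
    the pooled trait rate matrix column-block-wise so every module shares the
    common per-trait rate while trait correlations are preserved, then re-runs
    the whole computation on simulated Brownian tip data.
    """
    if nsim < 1:
        raise ValueError("nsim must be >= 1")
    partition.validate_for(Y.k)

    cov = phylo_covariance(tree, Y.taxa)
    inv_half, fwd_half, w = _covariance_roots(cov.C)
    gls_mean = w @ Y.Y
    Yt = inv_half @ (Y.Y - gls_mean)
    obs_rates = module_rates(Yt, partition, Y.k)
    r_mult, hi, lo = _max_min_ratio(obs_rates)

    # common per-trait rate over the columns that belong to some module
    all_cols = [c for name in partition.modules for c in partition.columns(name)]
    n, p = Yt.shape
    common = float((Yt[:, all_cols] ** 2).sum() / (n * len(all_cols)))
    if isotropic_null:
        R_null = common * np.eye(p)
    else:
        # rescale the pooled rate matrix block-wise: each module's mean
        # diagonal becomes the common rate, trait correlations preserved
        R = _pooled_rate_matrix(Yt, isotropic=False)
        d = np.ones(p)
        for name in partition.modules:
            cols = partition.columns(name)
            d[cols] = np.sqrt(common / obs_rates[name])
        R_null = R * np.outer(d, d)

    eigval, eigvec = np.linalg.eigh(R_null)
    A_R = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    rng = np.random.default_rng(seed)
    exceed = 0
    block = max(1, min(nsim, int(2e7 // (n * p))))
    done = 0
    cols_by_module = {name: partition.columns(name) for name in partition.modules}
    while done < nsim:
        m = min(block, nsim - done)
        Z = rng.standard_normal((m, n, p))
        X = fwd_half @ Z @ A_R.T
        a = np.einsum("i,mip->mp", w, X)
        Xt = inv_half @ (X - a[:, None, :])
        sim = np.stack(
            [
                (Xt[:, :, cols] ** 2).sum(axis=(1, 2)) / (n * len(cols))
                for cols in cols_by_module.values()
            ],
            axis=1,
        )
        sim_ratio = sim.max(axis=1) / sim.min(axis=1)
        exceed += int((sim_ratio >= r_mult).sum())
        done += m
    p_value = (1 + exceed) / (1 + nsim)

    return ModularityResult(
        sigma2_by_module=dict(sorted(obs_rates.items())),
        r_mult=r_mult,
        module_numerator=hi,
        module_denominator=lo,
        p_value=p_value,
        nsim=nsim,
        seed=seed,
    )


def within_module_clade_test(
    Y: ShapeMatrix,
    tree: Chronogram,
    groups: Mapping[str, str],
    module: Iterable[int],
    nsim: int = 9999,
    seed: int | None = None,
    isotropic_null: bool = False,
) -> RateTestResult:
    """Clade rate-ratio test restricted to one module's landmarks.

    Exactly :func:`~shaperate.rates.rate_ratio_test` on the module's columns
    (whitening is cross-trait independent, so subsetting before the transform
    is equivalent to subsetting after it).
    """
    Ym = subset_landmarks(Y, module)
    return rate_ratio_test(
        Ym, tree, groups, nsim=nsim, seed=seed, isotropic_null=isotropic_null
    )
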