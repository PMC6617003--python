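"""Generic Metropolis-within-Gibbs driver.

A model is a bundle of update blocks over a shared state dict.  Blocks
either sample exact full conditionals (Gibbs) or make adaptive
random-walk Metropolis proposals; step sizes adapt only during burn-in
so the kept draws target the exact posterior.  Chains run independently
from per-chain seeds; post burn-in draws are thinned and collected into
a :class:`PosteriorSamples` container with classic Gelman-Rubin
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core_data import MCMCSettings


class Block:
    """Base update block; subclasses mutate ``state`` in place."""

    name: str = "block"

    def update(self, state: dict, rng: np.random.Generator,
               adapt: bool) -> None:  # pragma: no cover - interface
        raise NotImplementedError

    def initial_logpost(self, state: dict) -> float | None:
        """Log target at the initial state, if the block can evaluate one."""
        return None

    @property
    def acceptance_rate(self) -> float | None:
        return None


class GibbsBlock(Block):
    """Exact full-conditional update: ``sampler(state, rng)`` returns a
    dict of state entries to overwrite."""

    def __init__(self, name: str, sampler: Callable[[dict, np.random.Generator], dict]):
        self.name = name
        self.sampler = sampler

    def update(self, state, rng, adapt):
        state.update(self.sampler(state, rng))


class RandomWalkBlock(Block):
    """Adaptive Gaussian random-walk Metropolis on one state entry.

    ``logpost(state)`` evaluates the log target as a function of the
    blocked entry (scalar or vector, proposed jointly).  An optional
    proposal covariance Cholesky factor shapes the jumps; the global
    scale adapts toward ``target_accept`` during burn-in only.
    """

    def __init__(self, name: str, key: str,
                 logpost: Callable[[dict], float],
                 step0: float = 0.1,
                 proposal_chol: np.ndarray | None = None,
                 target_accept: float = 0.35,
                 support: Callable[[np.ndarray], bool] | None = None):
        self.name = name
        self.key = key
        self.logpost = logpost
        self.step = float(step0)
        self.proposal_chol = proposal_chol
        self.target_accept = target_accept
        self.support = support
        self._adapt_count = 0
        self._accepted = 0
        self._proposed = 0

    def initial_logpost(self, state):
        return float(self.logpost(state))

    def update(self, state, rng, adapt):
        cur = np.atleast_1d(np.asarray(state[self.key], dtype=float))
        scalar = np.ndim(state[self.key]) == 0
        z = rng.standard_normal(cur.size)
        if self.proposal_chol is not None:
            z = self.proposal_chol @ z
        prop = cur + self.step * z
        ok = self.support is None or self.support(prop if not scalar else prop[0])
        accepted = False
        if ok:
            lp0 = self.logpost(state)
            state[self.key] = prop[0] if scalar else prop
            lp1 = self.logpost(state)
            if np.log(rng.uniform()) < lp1 - lp0:
                accepted = True
            else:
                state[self.key] = cur[0] if scalar else cur
        if adapt:
            self._adapt_count += 1
            # Robbins-Monro on log step size, vanishing gain
            gain = 1.0 / np.sqrt(self._adapt_count)
            self.step *= np.exp(gain * ((1.0 if accepted else 0.0) - self.target_accept))
        else:
            self._proposed += 1
            self._accepted += int(accepted)

    @property
    def acceptance_rate(self):
        if self._proposed == 0:
            return None
        return self._accepted / self._proposed


@dataclass
class PosteriorSamples:
    """Thinned multi-chain draws keyed by parameter name.

    Each array is indexed ``(chain, draw)`` for scalars or
    ``(chain, draw, dim)`` for vector parameters.
    """

    params: dict
    settings: MCMCSettings
    acceptance_rates: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """Draws pooled across chains (first axis = chain*draw)."""
        arr = self.params[name]
        return arr.reshape(-1, *arr.shape[2:])

    def scalar_names(self) -> list[str]:
        return [k for k, v in self.params.items() if v.ndim == 2]

    def summary(self) -> pd.DataFrame:
        """Posterior mean, SD, 2.5/97.5 percentiles and R-hat per scalar
        element (vector parameters expand to ``name[j]`` rows)."""
        rows = []
        rhats = gelman_rubin(self)
        for name, arr in self.params.items():
            flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
            for j in range(flat.shape[2]):
                x = flat[:, :, j].ravel()
                label = name if arr.ndim == 2 else f"{name}[{j}]"
                r = rhats[name]
                rows.append({
                    "parameter": label,
                    "mean": float(np.mean(x)),
                    "sd": float(np.std(x, ddof=1)),
                    "q025": float(np.quantile(x, 0.025)),
                    "q975": float(np.quantile(x, 0.975)),
                    "rhat": float(np.atleast_1d(r)[j]),
                })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        """Long columnar text dump: parameter, chain, draw, value."""
        frames = []
        for name, arr in self.params.items():
            flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
            C, D, P = flat.shape
            for j in range(P):
                label = name if arr.ndim == 2 else f"{name}[{j}]"
                frames.append(pd.DataFrame({
                    "parameter": label,
                    "chain": np.repeat(np.arange(C), D),
                    "draw": np.tile(np.arange(D), C),
                    "value": flat[:, :, j].ravel(),
                }))
        pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def gelman_rubin(samples: "PosteriorSamples | dict") -> dict:
    """Classic (split-free) Gelman-Rubin potential scale reduction.

    For each parameter: R-hat = sqrt(((n-1)/n * W + B/n) / W) with W the
    mean within-chain variance and B/n the variance of chain means.
    Vector parameters return elementwise R-hat arrays.  Raises on fewer
    than 2 chains, fewer than 10 draws, or zero within-chain variance.
    """
    params = samples.params if isinstance(samples, PosteriorSamples) else samples
    out = {}
    for name, arr in params.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim < 2 or arr.shape[0] < 2:
            raise ValueError(f"gelman_rubin needs >= 2 chains for {name!r}")
        C, n = arr.shape[0], arr.shape[1]
        if n < 10:
            raise ValueError(f"gelman_rubin needs >= 10 draws per chain for {name!r}")
        flat = arr.reshape(C, n, -1)
        W = flat.var(axis=1, ddof=1).mean(axis=0)
        chain_means = flat.mean(axis=1)
        B_over_n = chain_means.var(axis=0, ddof=1)
        if np.any(W == 0):
            raise ValueError(f"degenerate (constant) chains for parameter {name!r}")
        rhat = np.sqrt(((n - 1) / n * W + B_over_n) / W)
        out[name] = float(rhat[0]) if arr.ndim == 2 else rhat
    return out


def run(model, settings: MCMCSettings, seed: int | None = None) -> PosteriorSamples:
    """Run independent chains of the model's block sweep.

    ``model`` provides ``init_state(chain, rng) -> dict``,
    ``make_blocks(state) -> list[Block]`` (fresh per chain so adaptation
    state is not shared), ``track(state) -> dict`` of recorded
    quantities, and optionally ``on_keep(state, chain)`` for running
    accumulators over kept draws.
    """
    seeds = settings.resolve_seeds(seed)
    per_chain: list[dict] = []
    acc_rates: dict = {}
    for chain, chain_seed in enumerate(seeds):
        rng = np.random.default_rng(chain_seed)
        state = model.init_state(chain, rng)
        blocks = model.make_blocks(state)
        for blk in blocks:
            lp = blk.initial_logpost(state)
            if lp is not None and not np.isfinite(lp):
                raise ValueError(
                    f"non-finite log target at initialization of block {blk.name!r}")
        for _ in range(settings.burn_in):
            for blk in blocks:
                blk.update(state, rng, adapt=True)
        records: dict[str, list] = {}
        for _ in range(settings.n_keep):
            for _ in range(settings.thin):
                for blk in blocks:
                    blk.update(state, rng, adapt=False)
            tracked = model.track(state)
            for k, v in tracked.items():
                records.setdefault(k, []).append(np.array(v, dtype=float))
            if hasattr(model, "on_keep"):
                model.on_keep(state, chain)
        per_chain.append({k: np.stack(v) for k, v in records.items()})
        for blk in blocks:
            r = blk.acceptance_rate
            if r is not None:
                acc_rates.setdefault(blk.name, []).append(r)
    params = {k: np.stack([c[k] for c in per_chain]) for k in per_chain[0]}
    acc = {k: float(np.mean(v)) for k, v in acc_rates.items()}
    return PosteriorSamples(params=params, settings=settings, acceptance_rates=acc)


@dataclass
class SimpleModel:
    """Adapter turning explicit callables/blocks into an engine model.

    Useful for small targets (tests, diagnostics) without a bespoke
    model class.
    """

    init: Callable[[int, np.random.Generator], dict]
    blocks_factory: Callable[[dict], Sequence[Block]]
    tracked: Sequence[str]

    def init_state(self, chain, rng):
        return self.init(chain, rng)

    def make_blocks(self, state):
        return list(self.blocks_factory(state))

    def track(self, state):
        return {k: state[k] for k in self.tracked}
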