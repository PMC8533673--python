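"""Synthetic tabular data with the structures the method's claims rest on:
marginal (main-effect) signal of tunable strength, pure-noise features, and
pairwise interaction-only (XOR-type) signal with no marginal association.

All generators are pure functions of their spec: the same spec yields the
same bytes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .data import Dataset

_MAX_REDRAWS = 20


@dataclass(frozen=True)
class SynthSpec:
    """Generator settings.

    ``effect`` is the standardized mean shift between classes on each signal
    feature (features have unit variance, so 0.2 is a weak and 2+ a strong
    marginal signal).  ``label_noise`` is the probability of flipping each
    label after generation.
    """

    n: int = 200
    p_signal: int = 2
    p_noise: int = 8
    effect: float = 1.0
    xor_pairs: int = 0
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 20:
            raise ValueError("n must be >= 20")
        if self.p_signal + self.p_noise + 2 * self.xor_pairs < 1:
            raise ValueError("at least one feature is required")
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must lie in [0, 0.5)")


def _rng(spec: SynthSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(stream,)))


def _flip(y: np.ndarray, spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.label_noise > 0:
        flip = rng.random(y.size) < spec.label_noise
        y = np.where(flip, 1 - y, y)
    return y.astype(np.int8)


def gen_marginal(spec: SynthSpec) -> Dataset:
    """Marginal-signal data: balanced Bernoulli(0.5) labels; signal features
    are class-conditional normals shifted by ``effect``; noise features are
    independent standard normals.  Degenerate single-class draws are redrawn
    from an incremented stream (bounded)."""
    for attempt in range(_MAX_REDRAWS):
        rng = _rng(spec, attempt)
        y = (rng.random(spec.n) < 0.5).astype(np.int8)
        if 0 < y.sum() < spec.n:
            break
    else:  # pragma: no cover - probability ~2^-n per attempt
        raise RuntimeError("could not draw a two-class label vector")
    Xs = rng.normal(size=(spec.n, spec.p_signal)) + spec.effect * y[:, None]
    Xn = rng.normal(size=(spec.n, spec.p_noise))
    X = np.hstack([Xs, Xn])
    y = _flip(y, spec, rng)
    names = [f"s{j + 1}" for j in range(spec.p_signal)] + [
        f"n{j + 1}" for j in range(spec.p_noise)
    ]
    return Dataset(X, y, names, meta={"generator": "marginal", **asdict(spec)})


def gen_xor(spec: SynthSpec) -> Dataset:
    """Interaction-only data: for each planted pair the pair label is
    ``1[(x_a > 0) != (x_b > 0)]`` (a qualitative interaction: the direction
    of each member's effect depends on the other member); pair labels are
    combined by majority with a random tie-break bit; every planted feature
    has ~zero marginal association with the outcome.  ``p_noise`` standard
    normal noise features are appended."""
    if spec.xor_pairs < 1:
        raise ValueError("gen_xor needs xor_pairs >= 1")
    rng = _rng(spec, 0)
    k = spec.xor_pairs
    Xp = rng.normal(size=(spec.n, 2 * k))
    votes = np.zeros(spec.n)
    for i in range(k):
        votes += ((Xp[:, 2 * i] > 0) != (Xp[:, 2 * i + 1] > 0)).astype(int)
    tie = rng.random(spec.n) < 0.5
    y = np.where(votes * 2 == k, tie, votes * 2 > k).astype(np.int8)
    Xn = rng.normal(size=(spec.n, spec.p_noise))
    X = np.hstack([Xp, Xn])
    y = _flip(y, spec, rng)
    names = [f"xor{i + 1}{ab}" for i in range(k) for ab in ("a", "b")] + [
        f"n{j + 1}" for j in range(spec.p_noise)
    ]
    return Dataset(X, y, names, meta={"generator": "xor", **asdict(spec)})


def quantile_bin(values: np.ndarray, bins: int = 4) -> np.ndarray:
    """Integer-code a continuous column into quantile bins (exercises the
    categorical-encoding path with synthetic data)."""
    qs = np.quantile(values, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(qs, values).astype(np.float64)


def gen_dataset_battery(count: int, seed: int = 0) -> list[Dataset]:
    """A deterministic battery of datasets spanning weak (effect <= 0.3) and
    strong (effect >= 2) marginal regimes plus interaction-only datasets.

    Regimes cycle (weak, strong, xor); sizes are drawn from documented
    ranges: n in [100, 600], p_signal in [2, 5], p_noise in [5, 40].
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    master = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    out: list[Dataset] = []
    for i in range(count):
        n = int(master.integers(100, 601))
        p_signal = int(master.integers(2, 6))
        p_noise = int(master.integers(5, 41))
        sub_seed = int(master.integers(0, 2**31))
        regime = ("weak", "strong", "xor")[i % 3]
        if regime == "weak":
            spec = SynthSpec(n, p_signal, p_noise, effect=float(master.uniform(0.1, 0.3)),
                             seed=sub_seed)
            ds = gen_marginal(spec)
        elif regime == "strong":
            spec = SynthSpec(n, p_signal, p_noise, effect=float(master.uniform(2.0, 3.0)),
                             seed=sub_seed)
            ds = gen_marginal(spec)
        else:
            spec = SynthSpec(n, 0, p_noise, xor_pairs=int(master.integers(1, 3)),
                             seed=sub_seed)
            ds = gen_xor(spec)
        ds.meta["regime"] = regime
        out.append(ds)
    return out
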