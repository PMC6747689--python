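"""Synthetic datasets with the DILIrank benchmark shape.

The generator emulates a 450-compound hepatotoxicity panel: 12 fingerprint
blocks at their real bit widths (three 1024-bit hashed families, the
79-bit E-state and 166-bit MACCS keys, 881 PubChem keys, 307-bit
substructure keys and their count variant, 4860-bit Klekota-Roth keys and
counts, and 780-entry 2D atom pairs and counts) plus a 7-column
physicochemical descriptor table, with a 182/268 positive/negative class
split.

Class signal is planted per block: a leading set of "informative" binary
features fires with probability ``p1`` in hepatotoxicants and ``p0``
otherwise (Poisson rates for count blocks); descriptors can be mean-shifted
per class. All remaining features are class-independent background. Because
informative features are conditionally independent, the Bayes-optimal
accuracy of the generative model is computable and serves as the recovery
target for end-to-end tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import Mapping

import numpy as np

from ._seeds import derive_seed
from .io import FeatureBlock, LabeledDataset

DESCRIPTOR_BLOCK_ID = "DESCRIPTORS"
DESCRIPTOR_NAMES = ("AlogP", "MW", "nAR", "nHBA", "nHBD", "nRTB", "nR")

#: background sampling for the 7 descriptors: (kind, params)
_DESCRIPTOR_MODELS: dict[str, tuple] = {
    "AlogP": ("normal", 2.5, 1.5),
    "MW": ("normal", 350.0, 85.0),
    "nAR": ("normal", 1.6, 1.1),
    "nHBA": ("normal", 4.2, 2.0),
    "nHBD": ("normal", 1.8, 1.3),
    "nRTB": ("normal", 5.0, 2.8),
    "nR": ("normal", 2.6, 1.4),
}


@dataclass(frozen=True)
class BlockSpec:
    block_id: str
    kind: str  # binary | count
    width: int


#: the 12 fingerprint families at their real widths
DEFAULT_BLOCK_SPECS: tuple[BlockSpec, ...] = (
    BlockSpec("FP", "binary", 1024),
    BlockSpec("ExtendedFP", "binary", 1024),
    BlockSpec("GraphOnlyFP", "binary", 1024),
    BlockSpec("EstateFP", "binary", 79),
    BlockSpec("MaccsFP", "binary", 166),
    BlockSpec("PubchemFP", "binary", 881),
    BlockSpec("SubstructreFP", "binary", 307),
    BlockSpec("nSubstructreFP", "count", 307),
    BlockSpec("KRFP", "binary", 4860),
    BlockSpec("nKRFP", "count", 4860),
    BlockSpec("AP2DFP", "binary", 780),
    BlockSpec("nAP2DFP", "count", 780),
)


@dataclass(frozen=True)
class PlantedSignal:
    """Class-dependent rates for the first ``n_informative`` features of a
    block: Bernoulli p's for binary blocks, Poisson rates for count blocks."""

    n_informative: int
    p1: float
    p0: float


#: default planted signal: 3 informative bits in each of the two
#: top-ranked fingerprint families; with the 182/268 class split this puts
#: the generative model's Bayes-optimal accuracy at 0.802
DEFAULT_SIGNAL: dict[str, PlantedSignal] = {
    "ExtendedFP": PlantedSignal(3, 0.66, 0.34),
    "KRFP": PlantedSignal(3, 0.66, 0.34),
}


@dataclass
class GeneratorConfig:
    n_compounds: int = 450
    positive_fraction: float = 182.0 / 450.0
    block_specs: tuple[BlockSpec, ...] = DEFAULT_BLOCK_SPECS
    signal: Mapping[str, PlantedSignal] = field(default_factory=lambda: dict(DEFAULT_SIGNAL))
    descriptor_shift: Mapping[str, float] = field(default_factory=dict)  # name -> SD units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 2:
            raise ValueError("need at least two compounds")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must lie strictly in (0, 1)")
        widths = {s.block_id: s for s in self.block_specs}
        for bid, sig in self.signal.items():
            if bid not in widths:
                raise ValueError(f"signal names unknown block {bid!r}")
            spec = widths[bid]
            if sig.n_informative > spec.width:
                raise ValueError(f"block {bid!r}: more informative features than width")
            if spec.kind == "binary" and not (0 <= sig.p0 <= 1 and 0 <= sig.p1 <= 1):
                raise ValueError(f"block {bid!r}: Bernoulli rates must lie in [0, 1]")
            if sig.p0 < 0 or sig.p1 < 0:
                raise ValueError(f"block {bid!r}: rates must be non-negative")
        n_pos = round(self.n_compounds * self.positive_fraction)
        if n_pos < 1 or n_pos > self.n_compounds - 1:
            raise ValueError("infeasible class sizes")

    @property
    def n_positive(self) -> int:
        return round(self.n_compounds * self.positive_fraction)


def small_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Test-scale configuration: same panel layout and class balance, but
    fingerprint widths shrunk (128 bits for the two signal-bearing families,
    32 elsewhere) so the full pipeline runs in seconds."""
    specs = tuple(
        BlockSpec(s.block_id, s.kind, 128 if s.block_id in ("ExtendedFP", "KRFP") else 32)
        for s in DEFAULT_BLOCK_SPECS
    )
    return GeneratorConfig(block_specs=specs, seed=seed, **overrides)


def generate(config: GeneratorConfig) -> LabeledDataset:
    """Draw one dataset from the generative model; deterministic given seed."""
    n = config.n_compounds
    n_pos = config.n_positive
    rng = np.random.default_rng(derive_seed(config.seed, "labels"))
    y = np.zeros(n, dtype=int)
    y[rng.choice(n, size=n_pos, replace=False)] = 1
    ids = [f"CMPD-{i:04d}" for i in range(1, n + 1)]

    blocks: dict[str, FeatureBlock] = {}
    for spec in config.block_specs:
        brng = np.random.default_rng(derive_seed(config.seed, "block", spec.block_id))
        sig = config.signal.get(spec.block_id, PlantedSignal(0, 0.0, 0.0))
        if spec.kind == "binary":
            base = brng.uniform(0.02, 0.5, size=spec.width)
            rates = np.tile(base, (n, 1))
            if sig.n_informative:
                rates[y == 1, : sig.n_informative] = sig.p1
                rates[y == 0, : sig.n_informative] = sig.p0
            values = (brng.random((n, spec.width)) < rates).astype(float)
        else:  # count
            base = brng.uniform(0.1, 1.5, size=spec.width)
            rates = np.tile(base, (n, 1))
            if sig.n_informative:
                rates[y == 1, : sig.n_informative] = sig.p1
                rates[y == 0, : sig.n_informative] = sig.p0
            values = brng.poisson(rates).astype(float)
        names = [f"{spec.block_id}{j}" for j in range(spec.width)]
        blocks[spec.block_id] = FeatureBlock(
            block_id=spec.block_id,
            kind=spec.kind,
            compound_ids=ids,
            feature_names=names,
            values=values,
        )

    drng = np.random.default_rng(derive_seed(config.seed, "block", DESCRIPTOR_BLOCK_ID))
    cols = []
    for name in DESCRIPTOR_NAMES:
        _, mu, sd = _DESCRIPTOR_MODELS[name]
        x = drng.normal(mu, sd, size=n)
        shift = config.descriptor_shift.get(name, 0.0)
        if shift:
            x = x + shift * sd * y
        cols.append(x)
    blocks[DESCRIPTOR_BLOCK_ID] = FeatureBlock(
        block_id=DESCRIPTOR_BLOCK_ID,
        kind="continuous",
        compound_ids=ids,
        feature_names=list(DESCRIPTOR_NAMES),
        values=np.column_stack(cols),
    )
    return LabeledDataset(compound_ids=ids, labels=y, blocks=blocks)


# ---------------------------------------------------------------------------
# Bayes-optimal accuracy of the generative model


def _signal_terms(config: GeneratorConfig) -> tuple[list[tuple[float, float]], list[float]]:
    """Collect (p1, p0) per informative Bernoulli bit and the per-descriptor
    standardized mean shifts. Count-block signal is not supported."""
    bits: list[tuple[float, float]] = []
    kinds = {s.block_id: s.kind for s in config.block_specs}
    for bid, sig in config.signal.items():
        if sig.n_informative == 0:
            continue
        if kinds[bid] != "binary":
            raise ValueError(
                f"bayes_accuracy supports only Bernoulli (binary-block) signal; "
                f"block {bid!r} is {kinds[bid]}"
            )
        bits.extend([(sig.p1, sig.p0)] * sig.n_informative)
    shifts = [s for s in config.descriptor_shift.values() if s]
    return bits, shifts


def bayes_accuracy(config: GeneratorConfig, n_mc: int = 200_000) -> float:
    """Bayes-optimal accuracy of the configured generative model.

    Exact by enumeration over informative-bit patterns when the signal is
    purely Bernoulli with at most 20 bits; otherwise Monte Carlo over the
    informative-feature distribution (deterministic given config.seed).
    """
    pi1 = config.n_positive / config.n_compounds
    pi0 = 1.0 - pi1
    bits, shifts = _signal_terms(config)
    if not bits and not shifts:
        return max(pi1, pi0)

    if not shifts and len(bits) <= 20:
        acc = 0.0
        for pattern in product((0, 1), repeat=len(bits)):
            l1 = np.prod([p1 if x else 1 - p1 for x, (p1, _) in zip(pattern, bits)])
            l0 = np.prod([p0 if x else 1 - p0 for x, (_, p0) in zip(pattern, bits)])
            acc += max(pi1 * l1, pi0 * l0)
        return float(acc)

    # Monte Carlo: draw class, draw informative features, score the
    # log-likelihood ratio analytically, count correct MAP decisions.
    rng = np.random.default_rng(derive_seed(config.seed, "bayes"))
    ycls = (rng.random(n_mc) < pi1).astype(int)
    llr = np.full(n_mc, np.log(pi1) - np.log(pi0))
    for p1, p0 in bits:
        p = np.where(ycls == 1, p1, p0)
        x = (rng.random(n_mc) < p).astype(float)
        llr += x * (np.log(p1) - np.log(p0)) + (1 - x) * (np.log1p(-p1) - np.log1p(-p0))
    for shift in shifts:
        z = rng.normal(0.0, 1.0, n_mc) + shift * ycls  # standardized descriptor
        llr += shift * z - 0.5 * shift**2
    correct = np.where(llr > 0, ycls == 1, ycls == 0)
    return float(correct.mean())


def fingerprint_signal_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Test-scale data where only fingerprint blocks carry class signal."""
    return small_config(seed=seed, **overrides)


def descriptor_signal_config(seed: int = 0, shift: float = 1.2) -> GeneratorConfig:
    """Test-scale data where only the descriptor block carries class signal."""
    return small_config(
        seed=seed,
        signal={},
        descriptor_shift={name: shift for name in ("AlogP", "MW", "nHBD", "nRTB")},
    )
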