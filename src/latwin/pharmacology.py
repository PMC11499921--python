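"""Multichannel drug blockade via the Hill equation.

A drug is described by per-channel (IC50, Hill coefficient) pairs; the
block fraction of a channel at free concentration D is

    theta = [1 + (IC50 / D)^nH]^-1

with theta(0) = 0 taken as the continuous limit.  Blockade is applied to
a :class:`~latwin.myocyte.ConductanceScaling` by multiplying each channel
factor by (1 - theta); channels without a drug entry are unblocked.

The shipped amiodarone table is a documented, replaceable default drawn
from the pharmacology literature (amiodarone is a class III agent with
substantial I_Na, I_CaL and potassium-channel block); the dose presets
are 1.6 uM (minimal effective), 3.9 uM (maximal effective) and 8.0 uM
(toxic).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np

from .myocyte import CHANNELS, CHANNEL_INDEX, ConductanceScaling, ModelError


@dataclasses.dataclass(frozen=True)
class ChannelAffinity:
    """Half-maximal inhibitory concentration (uM) and Hill coefficient."""

    ic50_uM: float
    hill_coefficient: float
    source: str = ""

    def __post_init__(self):
        if not self.ic50_uM > 0:
            raise ModelError(f"ic50_uM must be > 0, got {self.ic50_uM}")
        if not self.hill_coefficient > 0:
            raise ModelError(f"hill_coefficient must be > 0, got {self.hill_coefficient}")


@dataclasses.dataclass(frozen=True)
class DrugSpec:
    """A named multichannel blocker; channels without entries are unblocked."""

    name: str
    channels: Mapping[str, ChannelAffinity]

    def __post_init__(self):
        for ch in self.channels:
            if ch not in CHANNEL_INDEX:
                raise ModelError(f"unknown channel {ch!r} in drug {self.name!r}")

    @classmethod
    def from_table(cls, name: str, table: Mapping[str, Mapping[str, float]]) -> "DrugSpec":
        return cls(name, {
            ch: ChannelAffinity(entry["ic50_uM"], entry["hill_coefficient"],
                                entry.get("source", ""))
            for ch, entry in table.items()
        })


@dataclasses.dataclass(frozen=True)
class BlockadeVector:
    """Per-channel block fractions theta, each in [0, 1]."""

    theta: np.ndarray

    def __post_init__(self):
        th = np.asarray(self.theta, dtype=float)
        if th.shape != (len(CHANNELS),):
            raise ModelError(f"blockade must have {len(CHANNELS)} entries")
        if not np.all(np.isfinite(th)) or np.any(th < 0) or np.any(th > 1):
            raise ModelError("block fractions must lie in [0, 1]")
        object.__setattr__(self, "theta", th)

    def __getitem__(self, channel: str) -> float:
        return float(self.theta[CHANNEL_INDEX[channel]])


#: Default amiodarone affinity table (replaceable data, not algorithm).
AMIODARONE = DrugSpec("amiodarone", {
    "INa": ChannelAffinity(3.0, 1.0, "fast-channel block, literature-range"),
    "ICaL": ChannelAffinity(5.8, 1.0, "L-type Ca block, literature-range"),
    "Ito": ChannelAffinity(20.0, 1.0, "transient-outward block, literature-range"),
    "IKur": ChannelAffinity(20.0, 1.0, "ultrarapid K block, literature-range"),
    "IKr": ChannelAffinity(1.0, 1.0, "rapid delayed-rectifier block, literature-range"),
    "IKs": ChannelAffinity(20.0, 1.0, "slow delayed-rectifier block, literature-range"),
    "IK1": ChannelAffinity(40.0, 1.0, "inward-rectifier block, literature-range"),
})

#: Dose presets (uM): therapeutic = {low, high}.
DOSE_PRESETS = {"none": 0.0, "low": 1.6, "high": 3.9, "toxic": 8.0}
THERAPEUTIC_DOSES = ("low", "high")


def hill_blockade(drug: DrugSpec, concentration_uM: float) -> BlockadeVector:
    """Per-channel block fractions at a free drug concentration (uM)."""
    d = float(concentration_uM)
    if d < 0:
        raise ModelError(f"concentration must be >= 0, got {d}")
    theta = np.zeros(len(CHANNELS))
    if d > 0:
        for ch, aff in drug.channels.items():
            theta[CHANNEL_INDEX[ch]] = 1.0 / (1.0 + (aff.ic50_uM / d) ** aff.hill_coefficient)
    return BlockadeVector(theta)


def apply_drug(blockade: BlockadeVector, base: ConductanceScaling) -> ConductanceScaling:
    """Compose a blockade with a base scaling: factor *= (1 - theta)."""
    return ConductanceScaling(base.factors * (1.0 - blockade.theta))
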