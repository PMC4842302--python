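"""Synthetic fingerprint universes with planted target families.

Background molecules get independent Bernoulli(bit_density) bits, so the
expected pairwise Tanimoto of two background molecules is
d / (2 - d) for density d. Each planted family shares a fixed random
core bit pattern of ``core_bit_count`` bits; every member adds its own
``noise_bit_count`` random bits drawn outside the core. With mostly
disjoint noise, the expected within-family Tanimoto is approximately
core / (core + 2 * noise).

The generator emits the same artifacts the real pipeline consumes: a
fingerprint mapping, an activity table (members active on their family's
target) and a labelled held-out test-pair list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .similarity import Fingerprint

SYNTHETIC_PROVIDER = "synthetic"


@dataclass(frozen=True)
class FamilySpec:
    """One planted target family."""

    target_id: str
    n_members: int
    core_bit_count: int
    noise_bit_count: int

    def expected_tc(self) -> float:
        """Approximate expected within-family Tanimoto (disjoint noise)."""
        denom = self.core_bit_count + 2 * self.noise_bit_count
        return self.core_bit_count / denom if denom else 0.0


@dataclass(frozen=True)
class SyntheticConfig:
    n_bits: int = 2048
    n_background_molecules: int = 400
    families: tuple = ()
    bit_density: float = 0.03
    pchembl_low: float = 5.5
    pchembl_high: float = 9.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.bit_density < 1.0):
            raise ValueError("bit_density must lie in (0, 1)")
        fams = tuple(FamilySpec(*f) if not isinstance(f, FamilySpec) else f
                     for f in self.families)
        for fam in fams:
            if fam.n_members < 1:
                raise ValueError(f"family {fam.target_id}: n_members must be >= 1")
            if fam.core_bit_count + fam.noise_bit_count > self.n_bits:
                raise ValueError(
                    f"family {fam.target_id}: core + noise bits exceed n_bits={self.n_bits}")
        object.__setattr__(self, "families", fams)


@dataclass
class SyntheticUniverse:
    """Generated fingerprints plus the activity table and labelled test pairs."""

    fingerprints: dict                # molecule_id -> Fingerprint
    activities: pd.DataFrame          # molecule_id, target_id, pchembl
    test_pairs: pd.DataFrame          # molecule_id, target_id, label (1 active / 0 inactive)
    families: tuple

    @property
    def background_ids(self) -> list:
        return [m for m in self.fingerprints if m.startswith("bg_")]

    def family_members(self, target_id: str) -> list:
        return [m for m in self.fingerprints if m.startswith(f"{target_id}_m")]


def _background_fp(rng: np.random.Generator, n_bits: int, density: float) -> Fingerprint:
    on = np.flatnonzero(rng.random(n_bits) < density)
    return Fingerprint(on_bits=frozenset(int(b) for b in on), provider_id=SYNTHETIC_PROVIDER)


def generate_null_universe(config: SyntheticConfig) -> dict:
    """Pure-background molecules only; for background fitting and calibration."""
    rng = np.random.default_rng(config.seed)
    return {
        f"bg_{i:05d}": _background_fp(rng, config.n_bits, config.bit_density)
        for i in range(config.n_background_molecules)
    }


def generate_universe(config: SyntheticConfig) -> SyntheticUniverse:
    """Background molecules plus planted families, with activities and labels.

    Fully deterministic under ``config.seed``. Family member fingerprints
    are core-pattern bits plus per-molecule noise bits drawn outside the
    core; members receive a pChEMBL value uniform in
    [pchembl_low, pchembl_high] against their family target. The test-pair
    list holds every (member, own target) positive and an equal number of
    (background molecule, target) negatives.
    """
    rng = np.random.default_rng(config.seed)
    fingerprints = {
        f"bg_{i:05d}": _background_fp(rng, config.n_bits, config.bit_density)
        for i in range(config.n_background_molecules)
    }
    act_rows = []
    pos_rows = []
    all_bits = np.arange(config.n_bits)
    for fam in config.families:
        core = rng.choice(all_bits, size=fam.core_bit_count, replace=False)
        outside = np.setdiff1d(all_bits, core, assume_unique=False)
        for j in range(fam.n_members):
            noise = rng.choice(outside, size=fam.noise_bit_count, replace=False)
            mol_id = f"{fam.target_id}_m{j:04d}"
            bits = frozenset(int(b) for b in core) | frozenset(int(b) for b in noise)
            fingerprints[mol_id] = Fingerprint(on_bits=bits, provider_id=SYNTHETIC_PROVIDER)
            pchembl = float(rng.uniform(config.pchembl_low, config.pchembl_high))
            act_rows.append((mol_id, fam.target_id, pchembl))
            pos_rows.append((mol_id, fam.target_id, 1))
    activities = pd.DataFrame(act_rows, columns=["molecule_id", "target_id", "pchembl"])
    neg_rows = []
    if config.families and config.n_background_molecules:
        bg_ids = sorted(m for m in fingerprints if m.startswith("bg_"))
        targets = [fam.target_id for fam in config.families]
        for _ in range(len(pos_rows)):
            mol = bg_ids[int(rng.integers(len(bg_ids)))]
            tgt = targets[int(rng.integers(len(targets)))]
            neg_rows.append((mol, tgt, 0))
    test_pairs = pd.DataFrame(pos_rows + neg_rows,
                              columns=["molecule_id", "target_id", "label"])
    return SyntheticUniverse(fingerprints=fingerprints, activities=activities,
                             test_pairs=test_pairs, families=config.families)


def expected_null_tc(bit_density: float) -> float:
    """E[TC] for two independent Bernoulli(d) bit vectors: d / (2 - d)."""
    return bit_density / (2.0 - bit_density)
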