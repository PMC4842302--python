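"""Activity-table curation into per-target ligand sets.

The preparation workflow: standardize structures (largest fragment,
molecular-weight cap), aggregate repeated target-ligand activities by
their geometric mean in concentration space (arithmetic mean of pChEMBL),
apply the activity threshold, drop under-populated targets, and cap
over-populated ones with seeded max-min diverse picking. Every filtering
step is counted in a curation report; malformed structures are skipped,
never fatal.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .similarity import FingerprintProvider, tanimoto_matrix

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("molecule_id", "smiles", "target_id", "pchembl")


class EmptyModelError(RuntimeError):
    """No target survived curation; a model cannot be built."""


@dataclass(frozen=True)
class ActivityRecord:
    molecule_id: str
    smiles: str
    target_id: str
    pchembl: float

    def __post_init__(self):
        if not self.smiles:
            raise ValueError("smiles must be non-empty")
        if not np.isfinite(self.pchembl):
            raise ValueError("pchembl must be finite")


@dataclass(frozen=True)
class CurationConfig:
    """Thresholds of the preparation workflow (defaults: the reference protocol)."""

    mw_max: float = 1000.0               # Daltons
    pchembl_min: float = 5.0             # 5 / 6 / 7 <=> 10 / 1 / 0.1 uM
    min_ligands_per_target: int = 5
    max_ligands_per_target: int = 3000
    diversity_seed: int = 0

    def __post_init__(self):
        if self.mw_max <= 0:
            raise ValueError("mw_max must be positive")
        if self.min_ligands_per_target < 1:
            raise ValueError("min_ligands_per_target must be >= 1")
        if self.max_ligands_per_target < self.min_ligands_per_target:
            raise ValueError("max_ligands_per_target must be >= min_ligands_per_target")


@dataclass(frozen=True)
class LigandSet:
    """A target's curated set of molecule identifiers."""

    target_id: str
    members: tuple

    def __post_init__(self):
        members = tuple(self.members)
        if len(members) != len(set(members)):
            raise ValueError(f"duplicate molecule_ids in ligand set {self.target_id}")
        if not members:
            raise ValueError("ligand set must be non-empty")
        object.__setattr__(self, "members", members)

    @property
    def n(self) -> int:
        return len(self.members)


def standardize_molecule(smiles: str, mw_max: float = 1000.0):
    """Largest fragment of a structure as canonical SMILES; None if rejected.

    Salts/fragments are dropped by keeping the fragment with the most heavy
    atoms (molecular weight breaks ties). Returns None for unparseable
    input or when the kept fragment's molecular weight exceeds ``mw_max``.
    """
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    mol = Chem.MolFromSmiles(smiles) if smiles else None
    if mol is None:
        return None
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    best = max(frags, key=lambda f: (f.GetNumHeavyAtoms(), Descriptors.MolWt(f)))
    if Descriptors.MolWt(best) > mw_max:
        return None
    return Chem.MolToSmiles(best)


def aggregate_activity(values: Sequence[float]) -> float:
    """Combine repeated activities of one target-ligand pair.

    The geometric mean in concentration space is the arithmetic mean of
    pChEMBL values (a negative log10 of molar activity).
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("cannot aggregate an empty activity list")
    if not all(np.isfinite(vals)):
        raise ValueError("activities must be finite")
    return float(np.mean(vals))


def diverse_subset(mol_ids: Sequence[str], fingerprints: Mapping[str, object],
                   k: int, seed: int = 0) -> list:
    """Seeded max-min (farthest-point) pick of k molecules on Tanimoto distance."""
    mol_ids = list(mol_ids)
    if k >= len(mol_ids):
        return mol_ids
    fps = [fingerprints[m] for m in mol_ids]
    tc = tanimoto_matrix(fps, fps)
    rng = np.random.default_rng(seed)
    start = int(rng.integers(len(mol_ids)))
    chosen = [start]
    min_dist = 1.0 - tc[start]
    for _ in range(k - 1):
        min_dist[chosen] = -1.0
        nxt = int(np.argmax(min_dist))
        chosen.append(nxt)
        min_dist = np.minimum(min_dist, 1.0 - tc[nxt])
    return [mol_ids[i] for i in sorted(chosen)]


def standardize_table(df: pd.DataFrame, config: CurationConfig) -> tuple:
    """Standardize structures and aggregate duplicate activities.

    Deduplicates by canonical structure within a target (identical
    structures under different identifiers collapse onto the first
    identifier, noted in the report). Returns (table, report_fragment)
    with one row per (molecule, target) carrying aggregated pChEMBL.
    """
    _check_columns(df)
    report = {"input_rows": int(len(df)), "unparseable": 0, "over_mw": 0,
              "duplicate_structures_merged": 0}
    std_cache: dict = {}
    for smi in df["smiles"].unique():
        std_cache[smi] = standardize_molecule(smi, config.mw_max)
    std = df["smiles"].map(std_cache)
    # count both failure modes: parse failure vs weight rejection
    for smi, cnt in df["smiles"].value_counts().items():
        if std_cache[smi] is None:
            from rdkit import Chem
            if Chem.MolFromSmiles(smi) is None:
                report["unparseable"] += int(cnt)
            else:
                report["over_mw"] += int(cnt)
    out = df.assign(smiles=std).dropna(subset=["smiles"])
    # one identifier per canonical structure
    canon_id = out.groupby("smiles", sort=True)["molecule_id"].transform("min")
    report["duplicate_structures_merged"] = int((canon_id != out["molecule_id"]).sum())
    out = out.assign(molecule_id=canon_id)
    agg = (out.groupby(["target_id", "molecule_id"], sort=True)
              .agg(smiles=("smiles", "first"), pchembl=("pchembl", aggregate_activity))
              .reset_index())
    report["aggregated_rows"] = int(len(agg))
    return agg, report


def build_ligand_sets(records: pd.DataFrame, config: CurationConfig,
                      fingerprints: Mapping[str, object] | None = None) -> tuple:
    """Per-target ligand sets from a standardized, aggregated activity table.

    Applies the pChEMBL threshold, the minimum-set-size filter, and the
    diverse-subset cap (which requires ``fingerprints`` for the affected
    targets). Returns (list of LigandSet, report dict).
    """
    _check_columns(records, need_smiles=False)
    # defensive re-aggregation keeps the pipeline idempotent
    records = (records.groupby(["target_id", "molecule_id"], sort=True)["pchembl"]
                      .apply(aggregate_activity).reset_index())
    report = {"rows_before_threshold": int(len(records))}
    kept = records[records["pchembl"] >= config.pchembl_min]
    report["rows_below_pchembl"] = int(len(records) - len(kept))
    sizes = kept.groupby("target_id")["molecule_id"].nunique()
    small = set(sizes[sizes < config.min_ligands_per_target].index)
    report["targets_below_min_ligands"] = len(small)
    kept = kept[~kept["target_id"].isin(small)]
    sets = []
    capped = 0
    for target_id, grp in kept.groupby("target_id", sort=True):
        members = sorted(grp["molecule_id"].unique())
        if len(members) > config.max_ligands_per_target:
            if fingerprints is None:
                raise ValueError(
                    f"target {target_id} exceeds max_ligands_per_target but no "
                    "fingerprints were supplied for diverse picking")
            members = diverse_subset(members, fingerprints,
                                     config.max_ligands_per_target,
                                     seed=config.diversity_seed)
            capped += 1
        sets.append(LigandSet(target_id=target_id, members=tuple(members)))
    report["targets_capped_to_max"] = capped
    report["targets_out"] = len(sets)
    report["ligand_rows_out"] = sum(ls.n for ls in sets)
    if not sets:
        raise EmptyModelError("no targets survived curation")
    return sets, report


def curate_table(df: pd.DataFrame, config: CurationConfig,
                 provider: FingerprintProvider | None = None) -> tuple:
    """Full curation: standardize + aggregate + filter + cap.

    ``provider`` is only consulted when a target exceeds the ligand cap and
    a diverse subset must be picked on real fingerprints.

    Returns (ligand sets, fingerprint mapping or None, merged report).
    """
    agg, rep1 = standardize_table(df, config)
    fingerprints = None
    need_cap = (agg.groupby("target_id")["molecule_id"].nunique()
                   > config.max_ligands_per_target).any()
    if need_cap and provider is not None:
        from .similarity import compute_fingerprints
        smiles_by_id = agg.drop_duplicates("molecule_id").set_index("molecule_id")["smiles"]
        fingerprints = compute_fingerprints(smiles_by_id.to_dict(), provider)
    sets, rep2 = build_ligand_sets(agg[["molecule_id", "target_id", "pchembl"]],
                                   config, fingerprints)
    return sets, fingerprints, {**rep1, **rep2}


def _check_columns(df: pd.DataFrame, need_smiles: bool = True) -> None:
    needed = set(REQUIRED_COLUMNS) if need_smiles else {"molecule_id", "target_id", "pchembl"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"activity table missing columns: {sorted(missing)}")


def save_ligand_sets(sets: Sequence[LigandSet], path) -> None:
    """TSV of (target_id, molecule_id), one row per set member."""
    with open(path, "w") as fh:
        fh.write("target_id\tmolecule_id\n")
        for ls in sets:
            for m in ls.members:
                fh.write(f"{ls.target_id}\t{m}\n")


def load_ligand_sets(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return [LigandSet(target_id=t, members=tuple(g["molecule_id"]))
            for t, g in df.groupby("target_id", sort=True)]
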