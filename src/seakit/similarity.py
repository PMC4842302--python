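"""Molecular representations and pairwise similarity.

Two families of representation are supported:

* sparse binary fingerprints (Morgan, atom pair, topological torsion,
  MACCS keys, Gobbi 2D pharmacophore) compared with the Tanimoto
  coefficient ``c / (a + b + c)``;
* SHED descriptors — a 10-vector of Shannon-entropy feature-pair
  descriptors, each in [0, 20] — compared by normalised Euclidean
  distance ``1 - d / (20 * sqrt(10))``.

Fingerprints are kept as exact on-bit sets (no folding) so Tanimoto
counts are exact.
"""

from __future__ import annotations

import hashlib
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

_SHED_NORM = 20.0 * math.sqrt(10.0)

BINARY_PROVIDERS = ("morgan", "atom_pair", "topological_torsion", "maccs", "pharmacophore_2d")
PROVIDERS = BINARY_PROVIDERS + ("shed",)


class ProviderMismatchError(ValueError):
    """Raised when two representations from different providers are compared."""


@dataclass(frozen=True)
class Fingerprint:
    """Sparse binary fingerprint: the set of on-bit indices of one molecule."""

    on_bits: frozenset
    provider_id: str = "unknown"

    def __post_init__(self):
        if not isinstance(self.on_bits, frozenset):
            object.__setattr__(self, "on_bits", frozenset(self.on_bits))

    def __len__(self) -> int:
        return len(self.on_bits)


@dataclass(frozen=True)
class ShedDescriptor:
    """10-dimensional SHED descriptor; each component lies in [0, 20]."""

    values: tuple
    provider_id: str = "shed"

    def __post_init__(self):
        vals = tuple(float(v) for v in self.values)
        if len(vals) != 10:
            raise ValueError(f"SHED descriptor must have 10 components, got {len(vals)}")
        for v in vals:
            if not (0.0 <= v <= 20.0) or not math.isfinite(v):
                raise ValueError(f"SHED component {v} outside [0, 20]")
        object.__setattr__(self, "values", vals)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient c / (a + b + c) of two binary fingerprints.

    Both-empty fingerprints compare as 0: featureless molecules should not
    look maximally similar.
    """
    if a.provider_id != b.provider_id:
        raise ProviderMismatchError(
            f"cannot compare fingerprints from providers {a.provider_id!r} and {b.provider_id!r}"
        )
    union = len(a.on_bits | b.on_bits)
    if union == 0:
        return 0.0
    return len(a.on_bits & b.on_bits) / union


def shed_similarity(a: ShedDescriptor, b: ShedDescriptor) -> float:
    """SHED similarity: 1 - Euclidean distance / (20 * sqrt(10))."""
    dist = float(np.linalg.norm(a.as_array() - b.as_array()))
    return 1.0 - dist / _SHED_NORM


def similarity(a, b) -> float:
    """Dispatch to tanimoto or shed_similarity by representation type."""
    if isinstance(a, ShedDescriptor) and isinstance(b, ShedDescriptor):
        return shed_similarity(a, b)
    if isinstance(a, Fingerprint) and isinstance(b, Fingerprint):
        return tanimoto(a, b)
    raise ProviderMismatchError(f"incomparable representations: {type(a).__name__} vs {type(b).__name__}")


# ---------------------------------------------------------------------------
# vectorised cross-set similarity
# ---------------------------------------------------------------------------

def _check_same_provider(fps: Sequence) -> str:
    pids = {fp.provider_id for fp in fps}
    if len(pids) > 1:
        raise ProviderMismatchError(f"mixed providers in one set: {sorted(pids)}")
    return next(iter(pids)) if pids else "unknown"

def pack_fingerprints(fps_a: Sequence[Fingerprint], fps_b: Sequence[Fingerprint]):
    """Pack two fingerprint lists into dense 0/1 matrices over the union of bits."""
    bits = sorted(set().union(*(fp.on_bits for fp in fps_a), *(fp.on_bits for fp in fps_b)))
    index = {b: i for i, b in enumerate(bits)}
    def mat(fps):
        m = np.zeros((len(fps), max(len(bits), 1)), dtype=np.float64)
        for r, fp in enumerate(fps):
            for b in fp.on_bits:
                m[r, index[b]] = 1.0
        return m
    return mat(fps_a), mat(fps_b)


def tanimoto_matrix(fps_a: Sequence, fps_b: Sequence) -> np.ndarray:
    """All-pairs similarity between two lists of representations.

    Binary fingerprints use exact Tanimoto via bit-matrix products; SHED
    descriptors use the normalised-Euclidean similarity. Shape (len(a), len(b)).
    """
    if len(fps_a) == 0 or len(fps_b) == 0:
        return np.zeros((len(fps_a), len(fps_b)))
    pa = _check_same_provider(fps_a)
    pb = _check_same_provider(fps_b)
    if pa != pb:
        raise ProviderMismatchError(f"cannot compare providers {pa!r} and {pb!r}")
    if isinstance(fps_a[0], ShedDescriptor):
        a = np.stack([fp.as_array() for fp in fps_a])
        b = np.stack([fp.as_array() for fp in fps_b])
        d = np.sqrt(np.maximum(
            (a * a).sum(1)[:, None] + (b * b).sum(1)[None, :] - 2.0 * a @ b.T, 0.0))
        return 1.0 - d / _SHED_NORM
    ma, mb = pack_fingerprints(fps_a, fps_b)
    inter = ma @ mb.T
    na = ma.sum(axis=1)[:, None]
    nb = mb.sum(axis=1)[None, :]
    union = na + nb - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        tc = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return tc


# ---------------------------------------------------------------------------
# providers
# ---------------------------------------------------------------------------

#: bin scheme used for the reference pharmacophore model
DEFAULT_PHARM_BINS = ((2, 3), (3, 4), (4, 5), (5, 6), (6, 7), (7, 20))

#: the Gobbi feature families entering the 10 SHED feature pairs
_SHED_FAMILIES = ("HD", "HA", "LH", "AR")  # donor, acceptor, hydrophobic, aromatic
_SHED_MAX_DIST = 20  # topological distances capped here; 20 bins bounds exp(H) at 20


class FingerprintProvider:
    """Computes one molecular representation; identified by ``key``.

    Fingerprints carry their provider's key so that representations from
    different providers (or differently parameterised ones) can never be
    compared silently.
    """

    def __init__(self, provider_id: str, **params):
        if provider_id not in PROVIDERS:
            raise ValueError(f"unknown provider {provider_id!r}; choose from {PROVIDERS}")
        self.provider_id = provider_id
        self.params = dict(params)
        self._impl = None  # lazily built RDKit machinery

    @property
    def key(self) -> str:
        if not self.params:
            return self.provider_id
        inner = ",".join(f"{k}={self.params[k]}" for k in sorted(self.params))
        return f"{self.provider_id}({inner})"

    @property
    def cache_token(self) -> str:
        return hashlib.sha1(self.key.encode()).hexdigest()[:12]

    # -- RDKit-backed computation ------------------------------------------

    def _build(self):
        from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
        from rdkit.Chem.Pharm2D import Gobbi_Pharm2D, Generate
        from rdkit.Chem.Pharm2D.SigFactory import SigFactory

        pid = self.params  # parameters mapping
        if self.provider_id == "morgan":
            gen = rdFingerprintGenerator.GetMorganGenerator(radius=int(pid.get("radius", 2)))
            self._impl = lambda mol: frozenset(gen.GetSparseCountFingerprint(mol).GetNonzeroElements())
        elif self.provider_id == "atom_pair":
            gen = rdFingerprintGenerator.GetAtomPairGenerator()
            self._impl = lambda mol: frozenset(gen.GetSparseCountFingerprint(mol).GetNonzeroElements())
        elif self.provider_id == "topological_torsion":
            gen = rdFingerprintGenerator.GetTopologicalTorsionGenerator()
            self._impl = lambda mol: frozenset(gen.GetSparseCountFingerprint(mol).GetNonzeroElements())
        elif self.provider_id == "maccs":
            self._impl = lambda mol: frozenset(MACCSkeys.GenMACCSKeys(mol).GetOnBits())
        elif self.provider_id == "pharmacophore_2d":
            points = tuple(pid.get("points", (2, 3)))
            if points not in ((2,), (2, 3)):
                raise ValueError("pharmacophore point counts restricted to (2,) or (2, 3)")
            bins = [tuple(b) for b in pid.get("bins", DEFAULT_PHARM_BINS)]
            for (lo, hi), (lo2, _hi2) in zip(bins, bins[1:]):
                if hi > lo2:
                    raise ValueError("pharmacophore bins must be ordered and non-overlapping")
            factory = SigFactory(
                Gobbi_Pharm2D.factory.featFactory,
                minPointCount=min(points),
                maxPointCount=max(points),
            )
            factory.SetBins(bins)
            factory.Init()
            self._impl = lambda mol: frozenset(Generate.Gen2DFingerprint(mol, factory).GetOnBits())
        elif self.provider_id == "shed":
            feat_factory = Gobbi_Pharm2D.factory.featFactory
            self._impl = lambda mol: _shed_values(mol, feat_factory)
        return self._impl

    def fingerprint(self, mol) -> Union[Fingerprint, ShedDescriptor]:
        """Representation for one RDKit molecule."""
        impl = self._impl or self._build()
        if self.provider_id == "shed":
            return ShedDescriptor(values=impl(mol), provider_id=self.key)
        return Fingerprint(on_bits=impl(mol), provider_id=self.key)


def _shed_values(mol, feat_factory) -> tuple:
    """SHED: per feature-type pair, exp of the Shannon entropy of the
    topological-distance distribution between the paired feature atoms.

    Distances are capped at 20 bonds and binned per bond, so each of the
    10 values lies in [0, 20] (0 when the molecule has no such pair).
    """
    from rdkit import Chem

    atoms_by_family = {fam: set() for fam in _SHED_FAMILIES}
    for feat in feat_factory.GetFeaturesForMol(mol):
        fam = feat.GetFamily()
        if fam in atoms_by_family:
            atoms_by_family[fam].update(feat.GetAtomIds())
    dmat = Chem.GetDistanceMatrix(mol)
    values = []
    for i, fam_a in enumerate(_SHED_FAMILIES):
        for fam_b in _SHED_FAMILIES[i:]:
            aa = sorted(atoms_by_family[fam_a])
            bb = sorted(atoms_by_family[fam_b])
            if fam_a == fam_b:
                dists = [dmat[x, y] for xi, x in enumerate(aa) for y in aa[xi + 1:]]
            else:
                dists = [dmat[x, y] for x in aa for y in bb if x != y]
            dists = [min(int(d), _SHED_MAX_DIST) for d in dists if d >= 1]
            if not dists:
                values.append(0.0)
                continue
            counts = np.bincount(dists, minlength=_SHED_MAX_DIST + 1)[1:]
            p = counts[counts > 0] / counts.sum()
            entropy = float(-(p * np.log(p)).sum())
            values.append(min(math.exp(entropy), 20.0))
    return tuple(values)


def make_provider(provider_id: str, **params) -> FingerprintProvider:
    """Provider factory; see :data:`PROVIDERS` for valid names."""
    return FingerprintProvider(provider_id, **params)


def compute_fingerprints(structures: Mapping[str, object], provider: FingerprintProvider) -> dict:
    """Map molecule_id -> representation for a mapping of id -> RDKit mol or SMILES."""
    from rdkit import Chem

    out = {}
    for mol_id, struct in structures.items():
        mol = Chem.MolFromSmiles(struct) if isinstance(struct, str) else struct
        if mol is None:
            raise ValueError(f"unparseable structure for {mol_id!r}")
        out[mol_id] = provider.fingerprint(mol)
    return out


# ---------------------------------------------------------------------------
# plain-text sidecar format: molecule_id <TAB> provider_key <TAB> payload
# ---------------------------------------------------------------------------

def save_fingerprints(fps: Mapping[str, object], path) -> None:
    with open(path, "w") as fh:
        for mol_id, fp in fps.items():
            if isinstance(fp, ShedDescriptor):
                payload = ",".join(f"{v:.6g}" for v in fp.values)
            else:
                payload = ",".join(str(b) for b in sorted(fp.on_bits))
            fh.write(f"{mol_id}\t{fp.provider_id}\t{payload}\n")


def load_fingerprints(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            mol_id, pid, payload = line.split("\t")
            if pid.startswith("shed"):
                out[mol_id] = ShedDescriptor(
                    values=tuple(float(v) for v in payload.split(",")), provider_id=pid)
            else:
                bits = frozenset(int(b) for b in payload.split(",") if b != "")
                out[mol_id] = Fingerprint(on_bits=bits, provider_id=pid)
    return out
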