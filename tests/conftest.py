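import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import seakit as sk

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: conditions for the synthetic null universe used across the suite
NULL_CONFIG = sk.SyntheticConfig(
    n_bits=2048, n_background_molecules=400, bit_density=0.03, seed=7)

#: planted families: size >= 20, expected within-family TC = 60/(60+2*10) = 0.75
FAMILIES = tuple(sk.FamilySpec(f"T{i:02d}", 25, 60, 10) for i in range(5))

# drug-like structures exercising the chemistry-backed providers and curation
DRUG_SMILES = [
    "CC(=O)Oc1ccccc1C(=O)O",            # aspirin
    "CC(=O)Nc1ccc(O)cc1",               # paracetamol
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",       # ibuprofen
    "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",     # caffeine
    "Clc1ccccc1-c1nc2ccccc2[nH]1",      # benzimidazole
    "OCC(O)C(O)C(O)C(O)CO",             # sorbitol
    "c1ccc2c(c1)cccc2",                 # naphthalene
    "CCN(CC)CCNC(=O)c1ccc(N)cc1",       # procainamide
    "CN(C)CCOC(c1ccccc1)c1ccccc1",      # diphenhydramine
    "NC(=O)c1ccc[nH]1",
    "CC(N)Cc1ccccc1",                   # amphetamine
    "Oc1ccc(CCN)cc1",                   # tyramine
    "COc1ccc(CCN)cc1",
    "CC(C)NCC(O)c1ccc(O)c(O)c1",        # isoprenaline
    "O=C(O)Cc1ccccc1",
    "NS(=O)(=O)c1ccc(Cl)cc1",
    "CCOC(=O)c1ccccc1N",
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "O=C(Nc1ccccc1)c1ccccc1",
    "CC1=CC(=O)CC(C)(C)C1",
]


@pytest.fixture(scope="session")
def null_universe():
    """400 random-bit molecules (the background fingerprint universe)."""
    return list(sk.generate_null_universe(NULL_CONFIG).values())


@pytest.fixture(scope="session")
def null_tc(null_universe):
    return sk.tanimoto_matrix(null_universe, null_universe)


@pytest.fixture(scope="session")
def null_model(null_universe, null_tc):
    """Background model fitted on the null universe at suite scale."""
    model = sk.SeaModel(size_min=10, size_max=100, size_step=10,
                        repetitions=60, random_state=1)
    return model.fit(null_universe, tc_matrix=null_tc)


@pytest.fixture(scope="session")
def planted_universe():
    """Null background plus five planted 25-member families (TC ~= 0.75)."""
    config = sk.SyntheticConfig(
        n_bits=NULL_CONFIG.n_bits,
        n_background_molecules=NULL_CONFIG.n_background_molecules,
        families=FAMILIES, bit_density=NULL_CONFIG.bit_density,
        seed=NULL_CONFIG.seed)
    return sk.generate_universe(config)


@pytest.fixture(scope="session")
def planted_model(planted_universe):
    """Background model fitted on the planted universe's background molecules."""
    fps = [planted_universe.fingerprints[m] for m in planted_universe.background_ids]
    model = sk.SeaModel(size_min=10, size_max=100, size_step=10,
                        repetitions=60, random_state=1)
    return model.fit(fps)


@pytest.fixture(scope="session")
def planted_targets(planted_universe):
    return {
        fam.target_id: [planted_universe.fingerprints[m]
                        for m in planted_universe.family_members(fam.target_id)]
        for fam in planted_universe.families
    }


@pytest.fixture()
def activity_table():
    """Tiny SMILES activity table: one big target, one small, one salt, one bad row."""
    rows = [(f"m{i:02d}", smi, "T_big", 6.0 + 0.1 * i)
            for i, smi in enumerate(DRUG_SMILES)]
    rows += [
        ("s01", "CCO.Cl", "T_small", 7.0),
        ("s02", "CCN", "T_small", 7.0),
        ("bad", "not_a_smiles", "T_big", 6.0),
        ("m00dup", "OC(=O)c1ccccc1OC(C)=O", "T_big", 8.0),  # aspirin again, new id
    ]
    return pd.DataFrame(rows, columns=["molecule_id", "smiles", "target_id", "pchembl"])


def brute_force_raw_score(fps_a, fps_b, ts):
    """Independent nested-loop oracle for the raw score."""
    total = 0.0
    for a in fps_a:
        for b in fps_b:
            union = len(a.on_bits | b.on_bits)
            tc = len(a.on_bits & b.on_bits) / union if union else 0.0
            if tc >= ts:
                total += tc
    return total
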