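import numpy as np
import pytest

from distmap_ema import (
    DistanceMap,
    TargetRecord,
    compute_distance_map,
    generate_decoys,
    generate_native,
    generate_pdm,
)
from distmap_ema.synthdata import contacts_from_pdm, random_sequence


def random_distance_map(L: int, seed: int, missing: int = 0) -> DistanceMap:
    """Random symmetric non-negative map with optionally missing residues."""
    rng = np.random.default_rng(seed)
    upper = rng.uniform(2.0, 20.0, size=(L, L))
    values = np.triu(upper, k=1)
    values = values + values.T
    observed = np.ones((L, L), dtype=bool)
    if missing:
        gone = rng.choice(L, size=missing, replace=False)
        observed[gone, :] = False
        observed[:, gone] = False
    return DistanceMap(values=values, observed=observed)


@pytest.fixture(scope="session")
def small_pool():
    """A 30-residue native, its target record, PDM, contacts and decoys."""
    L = 30
    native = generate_native(L, seed=11, target_id="TPOOL")
    target = TargetRecord("TPOOL", random_sequence(L, 12))
    pdm = generate_pdm(native, tau=0.4, seed=13)
    contacts = contacts_from_pdm(pdm)
    decoys = generate_decoys(native, [0.5, 2.0, 6.0], 3, seed=14)
    return {
        "native": native,
        "target": target,
        "pdm": pdm,
        "contacts": contacts,
        "decoys": decoys,
        "mdm_native": compute_distance_map(native),
    }
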