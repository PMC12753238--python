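import numpy as np
import pytest

from ionsite.structure import BindingSite, SiteSet
from ionsite.synthetic import SITE_LAYOUT, scenario, simulate, toy_structure_pdb


@pytest.fixture(scope="session")
def toy_pdb(tmp_path_factory):
    """Toy structure file whose residue-derived sites match the well layout."""
    path = tmp_path_factory.mktemp("structures") / "toy.pdb"
    path.write_text(toy_structure_pdb())
    return path


@pytest.fixture(scope="session")
def layout_siteset():
    """SiteSet built directly from the packaged well-layout coordinates."""
    return SiteSet(
        sites=[BindingSite(name=n, center=np.array(c)) for n, c in SITE_LAYOUT.items()]
    )


@pytest.fixture(scope="session")
def full_occupancy_run():
    """One 10 ns full-occupancy scenario trajectory with ground truth."""
    return simulate(scenario("full_occupancy", n_frames=100, seed=42))


def random_trajectory(seed: int, n_frames: int = 100, n_ions: int = 8,
                      n_protein: int = 6):
    """Uniform random-coordinate trajectory for brute-force oracle tests."""
    import pandas as pd

    from ionsite.trajectory import ParticleTable, Trajectory

    rng = np.random.default_rng(seed)
    species = (["ZN", "BCT"] * 4)[:n_ions]
    charges = [{"ZN": 2, "BCT": -1}[s] for s in species]
    roles = ["tracked"] * n_ions
    species += ["NA"] * 3 + ["CL"] * 3
    charges += [1] * 3 + [-1] * 3
    roles += ["background"] * 6
    species += ["PRT"] * n_protein
    charges += [0] * n_protein
    roles += ["protein"] * n_protein
    n = len(species)
    table = ParticleTable(
        pd.DataFrame({"id": np.arange(1, n + 1), "species": species,
                      "charge": charges, "role": roles})
    )
    coords = rng.uniform(0.0, 40.0, (n_frames, n, 3))
    times = np.arange(n_frames) / 10.0
    return Trajectory(particles=table, coords=coords, times=times, frame_rate=10.0)
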