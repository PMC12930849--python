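import pytest

from pkatraj import (
    EnsembleHandle,
    FrameSnapshot,
    SyntheticSpec,
    generate_peptide,
    generate_trajectory,
    load_ensemble,
)
from pkatraj.synthetic import write_topology


@pytest.fixture(scope="session")
def peptide_spec() -> SyntheticSpec:
    # Gly, Ala and several ionizable residues; 10 frames of coherent motion.
    return SyntheticSpec(
        sequence="GADNEKAHYR", n_frames=10, motion_amplitude=1.0, seed=7,
        timestep_ps=100.0,
    )


@pytest.fixture(scope="session")
def peptide(peptide_spec) -> FrameSnapshot:
    return generate_peptide(peptide_spec)


@pytest.fixture(scope="session")
def ensemble_paths(tmp_path_factory, peptide, peptide_spec):
    d = tmp_path_factory.mktemp("ensemble")
    top = write_topology(peptide, d / "topology.pdb")
    traj = generate_trajectory(peptide, peptide_spec, d / "trajectory.pdb")
    return top, traj


@pytest.fixture()
def ensemble(ensemble_paths, peptide_spec) -> EnsembleHandle:
    top, traj = ensemble_paths
    return load_ensemble(top, traj, stride=1, timestep_ps=peptide_spec.timestep_ps)
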