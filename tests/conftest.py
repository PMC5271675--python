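import numpy as np
import pytest

import dyncomp as dc


@pytest.fixture(scope="session")
def bench_truth(tmp_path_factory):
    """The canonical planted benchmark: 12 residues, 500 frames, 1 switch
    following 1 domain block, written as a multi-model PDB."""
    spec = dc.two_state_trajectory_spec(n_frames=500, seed=0)
    path = tmp_path_factory.mktemp("bench") / "trajectory.pdb"
    return dc.generate_trajectory(spec, str(path))


@pytest.fixture(scope="session")
def bench_traj(bench_truth):
    return dc.load_trajectory(bench_truth.path)


@pytest.fixture(scope="session")
def bench_result(bench_traj):
    """Full pipeline run at the method's default cutoffs (5, 15, 0.95, 0.75)."""
    return dc.run_pipeline(bench_traj, dc.PipelineConfig(seed=0))
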