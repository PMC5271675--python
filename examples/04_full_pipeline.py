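"""The full pipeline on a generated trajectory, from PDB to community PDB.

Generates the canonical 12-residue, 500-frame benchmark trajectory (one
side-chain switch riding one domain motion), loads it back through the PDB
reader, and runs every stage at the method's default cutoffs: 5 A contacts,
15 A CA-CA pairs, 0.95 cluster correlation, 0.75 network coupling.  All
tables, the GraphML network, per-community PDB files and the reproducibility
manifest are written to ./pipeline_output.
"""

from dyncomp import (
    PipelineConfig,
    generate_trajectory,
    load_trajectory,
    run_pipeline,
    two_state_trajectory_spec,
)

spec = two_state_trajectory_spec(n_frames=500, seed=0)
truth = generate_trajectory(spec, "benchmark_trajectory.pdb")
traj = load_trajectory(truth.path)

result = run_pipeline(traj, PipelineConfig(seed=0), outdir="pipeline_output")

for key, value in result.counts.items():
    print(f"{key}: {value}")
((a, b, weight),) = result.graph.edges
print(f"switch-domain coupling: {weight:.3f}")

# The pipeline recovers exactly the planted structure: 1 multimodal
# side-chain series (the switch), 1 domain component (the cross-hinge CA
# pairs), 1 edge coupling them (absolute average DCC ~0.94 >= 0.75) and one
# community containing both - the molecular-switch motif the framework is
# built to isolate.
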