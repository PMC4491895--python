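"""Full pipeline on a synthetic system with known coupling.

Writes the time-series TSV and reference PDB, runs embedding ->
recurrence -> joint counting -> networks -> centralities, and prints the
residues the joint-recurrence weighted network flags as significant.
"""

import tempfile
import warnings
from pathlib import Path

from jrpnet import pipeline, synth

warnings.simplefilter("ignore", UserWarning)

system = synth.SyntheticSystem(
    n_residues=12, n_frames=1000,
    coupling_pairs=frozenset({(2, 5), (3, 9)}), coupling_strength=0.8, seed=1,
)
workdir = Path(tempfile.mkdtemp())
synth.write_series_tsv(workdir / "series.tsv", synth.generate_series(system),
                       system.residue_ids)
synth.write_ca_pdb(workdir / "reference.pdb",
                   synth.generate_reference_coordinates(system), system.residue_ids)

config = pipeline.RunConfig(
    series_path=str(workdir / "series.tsv"),
    pdb_path=str(workdir / "reference.pdb"),
    out_dir=str(workdir / "out"),
)
result = pipeline.run_pipeline(config)

table = result["tables"]["jrp_weighted"]
print("joint-recurrence weighted network, per-residue centrality z-scores:")
print(table[["residue_id", "z_B", "z_C"]].round(2).to_string(index=False))

top = table.sort_values("z_B", ascending=False).head(4)
print(f"\ntop-betweenness residues: {list(top['residue_id'])}")
print(f"artifacts written under {workdir / 'out'} (edge lists, centrality")
print("tables, a Markdown report and a manifest that reproduces the run).")
print("Residues participating in the latent couplings (2, 3, 5, 9) carry the")
print("strongest joint-recurrence edges and tend to dominate the rankings.")
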