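"""Calibrate recurrence thresholds and count joint recurrences.

Each residue's threshold epsilon is chosen so its recurrence matrix has a
3% recurrence rate (ones over all matrix cells, diagonal included).  Two
residues sharing a latent driver then recur simultaneously far more often
than an independent pair.
"""

from jrpnet import embedding, recurrence, synth

system = synth.SyntheticSystem(
    n_residues=6, n_frames=1000,
    coupling_pairs=frozenset({(2, 5)}), coupling_strength=0.8, seed=1,
)
series = synth.generate_series(system)

matrices = {}
for rid, z in zip(system.residue_ids, series):
    params, _ = embedding.select_embedding(z)
    states = embedding.embed(z, params)
    cal = recurrence.calibrate_epsilon(states, target_rate=0.03)
    matrices[rid] = recurrence.recurrence_matrix(states, cal.epsilon, rid)
    print(f"residue {rid}: eps={cal.epsilon:.3f}, achieved rate={cal.achieved_rate:.5f}, "
          f"{states.shape[0]} states")

counts, n_common = recurrence.joint_recurrence_counts(matrices)
print(f"\njoint recurrences over the common window of {n_common} states:")
print(f"  coupled pair (2,5):    {counts[(2, 5)]}")
uncoupled = {k: v for k, v in counts.items() if not set(k) & {2, 5}}
print(f"  uncoupled pairs range: {min(uncoupled.values())}..{max(uncoupled.values())}")
print("\nEvery residue hits the 3% target almost exactly (quantile calibration);")
print("the coupled pair accumulates clearly more simultaneous recurrences than")
print("any independent pair, which is the signal the edge weights encode.")
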