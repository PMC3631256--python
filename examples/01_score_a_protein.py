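"""Score one protein for intrinsic disorder and print its profile.

The built-in predictor averages pairwise disorder-propensity energies
over a sliding window and maps the window energy through a logistic
calibration; residues with score >= 0.5 are called disordered.
"""

from virodisorder import DisorderProfile, PredictorSpec, predict_scores

# an ordered, aromatic-rich stretch followed by a disordered, E/P/K-rich one
sequence = "WFYILMWFYILMWFYILMWFYILMWFYILM" + "EPKSQEPKSQEPKSQEPKSQEPKSQEPKSQ"

spec = PredictorSpec()  # window 25, threshold applied downstream
scores = predict_scores(sequence, spec)
profile = DisorderProfile.from_sequence("demo", sequence, spec)

print(f"length          : {profile.length}")
print(f"disordered      : {profile.n_disordered} residues")
print(f"percent disorder: {profile.percent_disorder:.1f}%")
print()
print("pos  aa  score")
for i in (0, 14, 29, 30, 45, 59):
    print(f"{i + 1:>3}  {sequence[i]}   {scores[i]:.3f}")
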