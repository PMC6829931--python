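"""Generate a small labelled synthetic dataset and extract the five
per-trial features.

Each trial is a 50 Hz sequence of 32x32 seat-pressure frames; the feature
vector is (ASV, SD_LatCOP, SD_LonCOP, SD_LRratio, SD_FBratio). The group
means show each pattern's signature: TLF moves the longitudinal COP and
front/back ratio, TR the lateral COP and left/right ratio, SE a smaller
lateral signature.
"""

from seatsense import FEATURE_NAMES, SimulationParams, feature_table, simulate_dataset

params = SimulationParams(n_subjects=4, reps=6, duration=1.5, seed=7)
dataset = simulate_dataset(params)
print(f"{len(dataset)} trials ({params.n_subjects} subjects x 2 sides x 3 tasks x {params.reps} reps)")

table = feature_table(dataset.trials)
print("\nper-class feature means:")
print(table.groupby("label")[list(FEATURE_NAMES)].mean().round(3))
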