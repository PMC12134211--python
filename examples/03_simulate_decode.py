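"""Simulate a 4000-trap genotyping chip and decode it.

Generates per-trap, per-round, per-channel signals with no-signal
traps, double-signal (two-clone) traps and per-round colour errors at
the study rate, then runs the threshold/dominance/error-correction
decoder and scores it against the generator's ground truth.
"""

from poolscreen.pipeline import RunConfig, run_simulate_decode
from poolscreen.synthetic import GenotypingSimConfig

cfg = RunConfig(
    genotyping=GenotypingSimConfig(
        n_traps=4000, occupancy_prob=0.8, n_barcodes=85,
        p_round_error=0.038, p_no_signal=0.15, p_double_signal=0.05,
    ),
    seed=1,
)
res = run_simulate_decode(cfg)
print(res.summary.to_string())
print()
print("vs ground truth on signal-producing traps:")
print(res.confusion.to_string())
print()
print("decoded_fraction is the yield of usable genotypes per occupied trap;")
print("frac_wrong is the rare misassignment the distance-3 code keeps near 0.002.")
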