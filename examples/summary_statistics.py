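"""Work with published-style summary tables: Wilson CIs, Fisher tests,
count-chain reconstruction.

Quality-screening papers report, per pool and filter step, the sample
size, the percentage flagged and a 95% Wilson interval, comparing pools
with Fisher exact tests.  These primitives let you reproduce or check
such tables from the printed numbers alone.
"""

from wmquality import (fisher_exact, reconstruct_step_counts, relative_loss,
                       round_half_up, wilson_ci)

# 3 of 40 lab-tested participants flagged as anomalous
lo, hi = wilson_ci(3, 40)
print(f"3/40 flagged: {round_half_up(100 * 3 / 40)}% "
      f"[{round_half_up(lo)}, {round_half_up(hi)}]")

# rebuild a filter chain from printed percentages: initial N=196,
# per-step flag rates 17.3%, 42.0%, 27.7%
chain = reconstruct_step_counts(196, [17.3, 42.0, 27.7])
print("reconstructed (n_in, n_flagged) per step:", chain)
final_n = chain[-1][0] - chain[-1][1]
print(f"final retained: {final_n} of 196 "
      f"({round_half_up(100 * final_n / 196)}%)")

# compare two pools' flag counts: 34/196 vs 28/300 anomalous
p = fisher_exact(34, 196 - 34, 28, 300 - 28)
print(f"Fisher exact p for 34/196 vs 28/300: {p:.4f}")

# retention dropping from 87.6% to 72.6% is a relative loss of:
print(f"relative loss: {relative_loss(87.6, 72.6)}%")
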