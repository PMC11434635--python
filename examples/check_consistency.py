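"""Consistency diagnostics for the two built-in client judgment matrices.

For each matrix we print lambda_max, CI and CR.  A CR above 0.1 means the
judgments contradict each other too much to trust the derived weights (the
initial matrices); the refined matrices fall comfortably below the threshold.
"""

from ahp_refine import consistency, compute_weights
from ahp_refine.datasets import (
    client1_initial, client1_refined, client2_initial, client2_refined,
)

for fn in (client1_initial, client1_refined, client2_initial, client2_refined):
    M = fn()
    rep = consistency(M)
    w = compute_weights(M)
    verdict = "consistent" if rep.consistent else "INCONSISTENT"
    print(f"{fn.__name__:16s} lambda_max={rep.lambda_max:.4f} "
          f"CI={rep.ci:.4f} CR={rep.cr:.3f} -> {verdict}")
    print("                 weights:",
          " ".join(f"{l}={x:.3f}" for l, x in zip(M.labels, w.weights)))
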