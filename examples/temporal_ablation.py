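"""Does temporal credit assignment matter?  STBP vs. SDBP.

The order-coded task hides the class label entirely in spike timing: both
classes drive every input at identical mean rates, but class 0 fires group
A one step before group B inside each event and class 1 the reverse.  A
rate-only classifier is at chance here.  Deleting the cross-time gradient
terms (SDBP) leaves the forward dynamics intact but misassigns credit, so
full STBP should reach higher held-out accuracy on seed-paired runs.
"""

from stbp import (
    LIFConfig,
    SurrogateSpec,
    TaskSpec,
    TrainConfig,
    make_temporal_pattern_task,
    parse_architecture,
)
from stbp.training import ablate_temporal

task = make_temporal_pattern_task(
    TaskSpec(n_classes=2, n_inputs=20, T=10, n_samples=300, seed=1,
             n_events=3, p_fire=0.7)
)
chain = parse_architecture("20-30-2")
lif = LIFConfig(tau=0.5, v_th=0.2, T=10)
cfg = TrainConfig(optimizer="adam", lr=0.02, epochs=15, batch_size=64,
                  surrogate=SurrogateSpec("rectangular", 1.0))
df = ablate_temporal(task, chain, range(5), cfg, lif)

print(df.pivot(index="seed", columns="method", values="test_acc").round(3))
print(
    f"\nmean STBP {df.attrs['stbp_mean']:.3f} vs mean SDBP "
    f"{df.attrs['sdbp_mean']:.3f}; paired sign test p = {df.attrs['sign_test_p']:.3f}."
    "\nA positive gap shows the temporal gradient terms help on data whose"
    "\nclass structure lives in spike timing rather than spike counts."
)
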