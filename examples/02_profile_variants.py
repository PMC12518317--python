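"""Analytic complexity accounting across the ablation grid.

Builds each structural variant (M1 baseline ... M9 full network) at scale
preset s, folds batch norm into the convolutions (the deployment form whose
budgets the published tables quote), and prints parameters and
multiply-accumulate FLOPs. Directions to notice: the split-and-concatenate
backbone (M2) and the depthwise head (M4) shave parameters off the baseline,
attention (M3) adds them, and the full network (M9) is lighter than M3.
"""

from cnatnet import VARIANT_FLAGS, build_variant, oracle_param_count, \
    profile_network

print(f"{'variant':<9} {'flags':<17} {'params (M)':>10} {'MAC-FLOPs (B)':>14}")
for variant in sorted(VARIANT_FLAGS):
    net = build_variant(variant, scale="s", num_classes=1000)
    net.fuse()
    report = profile_network(net, input_size=224)
    flags = "".join("+-"[not f] for f in VARIANT_FLAGS[variant])
    print(f"{variant:<9} C2S2/AnC2f/DW {flags}  {report.params_m:>10} "
          f"{report.flops_b:>14}")

net = build_variant("M1", scale="s", num_classes=1000)
net.fuse()
print(f"\nM1 exact learnable scalars (fused): {oracle_param_count(net):,}")
print("per-block breakdown for M9:")
net9 = build_variant("M9", scale="s", num_classes=1000).fuse()
print(profile_network(net9, input_size=224).table())
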