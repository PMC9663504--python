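"""Division-orientation statistics on synthetic cell doublets.

Generates two doublet populations emulating EdU-labelled division pairs
— one dividing longitudinally (elongation phase), one transversally
(thickening phase) — then summarises the axial angles and compares the
groups with the Welch and permutation tests.
"""

from bulkybone import compare_groups, summarize
from bulkybone.synth import (DoubletGenParams, gen_doublets,
                             truncated_normal_mean)

long_ = gen_doublets(DoubletGenParams(n=100, mean_angle=20, sd_angle=15,
                                      seed=11)).angles()
trans = gen_doublets(DoubletGenParams(n=100, mean_angle=70, sd_angle=15,
                                      seed=22)).angles()

for name, angles, mu in (("longitudinal", long_, 20), ("transversal", trans, 70)):
    s = summarize(angles)
    print(f"{name:13s}: n={s.n} mean={s.mean:.1f} deg "
          f"(generator truth {truncated_normal_mean(mu, 15):.1f}) "
          f"median={s.median:.1f} IQR=[{s.q1:.1f}, {s.q3:.1f}] "
          f"transversal fraction={s.fraction_transversal:.2f}")

welch = compare_groups(long_, trans, "welch_t")
perm = compare_groups(long_, trans, "permutation", seed=33)
print(f"\nWelch t-test      : t={welch.statistic:.2f}, p={welch.p_value:.3g}")
print(f"permutation test  : p={perm.p_value:.3g} (10,000 resamples)")
print()
print("Angles are axial data folded into [0, 90] degrees against the "
      "proximo-distal bone axis: 0 = longitudinal division (elongation), "
      "90 = transversal (thickening).  The two phases separate decisively, "
      "the synthetic analogue of the longitudinal-to-transversal switch "
      "seen in growing and regenerating cartilage.")
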