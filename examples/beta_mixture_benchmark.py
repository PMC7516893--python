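"""Head-to-head index comparison on the analytic beta-mixture benchmark.

Data on (0,1) come from a two-component beta mixture; a Bayes-optimal
threshold classifier provides the latent representation.  The
representational heterogeneity (RRH) correctly reports 2 effective
components at equal weights and exactly 1 when the components coincide;
the distance-based comparators do neither.
"""

from renyihet import bmm_comparator_indices, bmm_rrh, optimal_threshold

print("separated components, shapes (5, 20):")
print("theta1   tau     RRH(q=1)  Qe       F2       L1")
for theta1 in [0.5, 0.6, 0.75, 0.9, 0.99]:
    theta = (theta1, 5.0, 20.0)
    tau = optimal_threshold(theta).tau
    rrh = bmm_rrh(theta, 1.0).between
    comp1 = bmm_comparator_indices(theta, 1.0, u=1.0)
    comp2 = bmm_comparator_indices(theta, 2.0, u=1.0)
    print(f"{theta1:5.2f}  {tau:6.3f}  {rrh:8.4f}  {comp1['Qe']:7.4f}  "
          f"{comp2['Fq']:7.4f}  {comp1['Lq']:7.4f}")

print("\nRRH is concave with peak 2 at equal weights; F2 paradoxically rises"
      "\nas the prior skews (a transfer-principle violation) and L1 never"
      "\nreaches 2.")

print("\noverlapping components, shapes (5, 5):")
for theta1 in [0.5, 0.75, 0.95]:
    theta = (theta1, 5.0, 5.0)
    rrh = bmm_rrh(theta, 1.0).between
    lq = bmm_comparator_indices(theta, 1.0, u=1.0, self_distance="expected")["Lq"]
    print(f"theta1={theta1:4.2f}: RRH={rrh:.4f}  L1={lq:.4f}")
print("RRH alone identifies the single effective component (value 1).")
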