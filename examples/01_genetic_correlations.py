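"""Why trait grouping uses QTL positions, not correlations.

Evaluates the closed-form genetic correlation between two traits controlled by
tightly linked or pleiotropic QTL.  The point: even fully pleiotropic trait
pairs can show any genetic correlation in [-1, 1] depending on effect signs and
sizes, so correlation-based grouping would miss co-localized QTL.
"""

from hotqtl import (
    DigenicModel,
    genetic_correlation_digenic,
    genetic_correlation_pleiotropic,
    monogenic_linked_correlation,
    phenotypic_correlation,
)

print("Two digenic traits on linked loci Qi-Qj-Qk-Ql, effects a=(1,-1), b=(1,-1):")
for d in [(1, 5, 1), (2, 2, 2), (3, 1, 3)]:
    rho = genetic_correlation_digenic(DigenicModel(1, -1, 1, -1, *d))
    print(f"  distances {d} cM -> rho_G = {rho:+.3f}")
print("Same loci, trait-2 effects flipped to b=(-1,1):")
rho = genetic_correlation_digenic(DigenicModel(1, -1, -1, 1, 1, 5, 1))
print(f"  distances (1, 5, 1) cM -> rho_G = {rho:+.3f}")

print("\nTwo traits sharing both QTL (full pleiotropy, unlinked pair):")
for effects in [(5, 2, 2, -5), (2, 2, 2, 2), (5, 2, 2, 5)]:
    rho = genetic_correlation_pleiotropic(*effects)
    print(f"  effects {effects} -> rho_G = {rho:+.3f}")

print("\nMonogenic traits, QTL d cM apart (same effect direction):")
for d in [0.0, 10.0, 34.657, 100.0]:
    print(f"  d = {d:7.3f} -> rho_G = {monogenic_linked_correlation(d):+.3f}")

rho_p = phenotypic_correlation(-0.196, 0.189, 0.560, 0.363)
print(f"\nNegative genetic and positive residual correlation can cancel:"
      f"\n  rho_G=-0.196, rho_E=+0.189, h2=(0.560, 0.363) -> rho_P = {rho_p:+.3f}")
print("So near-zero phenotypic correlation does not rule out shared QTL.")
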