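"""Score a pool of perturbed models against a toy homodimer with LDDT.

Builds a two-chain synthetic target, perturbs it at increasing noise levels,
and prints global LDDT, inter-chain LDDT (iLDDT), the contact-augmented
variant and superposition RMSD for each model. LDDT is the fraction of
reference interatomic distances preserved within 0.5/1/2/4 Å; values near 1
mean near-native local geometry, and the augmented variant additionally
penalizes contacts that exist only in the model.
"""

from emakit import (
    LddtParams,
    PoolSpec,
    lddt_score,
    make_model_pool,
    make_target,
    map_chains,
    superpose_rmsd,
)

target = make_target(n_chain_classes=1, copies_per_class=[2], residues_per_chain=15, seed=42)
pool = make_model_pool(target, PoolSpec.from_sigma_grid([0.0, 0.5, 1.0, 2.0, 4.0], 2, seed=7))

print(f"target: {len(target.chains)} chains, {target.n_residues} residues\n")
print(f"{'model':<10} {'sigma':>5} {'LDDT':>6} {'iLDDT':>6} {'augLDDT':>8} {'RMSD/Å':>7}")
sigmas = [0.0, 0.0, 0.5, 0.5, 1.0, 1.0, 2.0, 2.0, 4.0, 4.0]
for model, sigma in zip(pool, sigmas):
    mapping = map_chains(model, target)
    std = lddt_score(target, model, mapping).global_
    inter = lddt_score(target, model, mapping, LddtParams(interchain_only=True)).global_
    aug = lddt_score(target, model, mapping, LddtParams(augmented=True)).global_
    rmsd = superpose_rmsd(model, target, mapping)
    print(f"{model.id:<10} {sigma:>5.1f} {std:>6.3f} {inter:>6.3f} {aug:>8.3f} {rmsd:>7.2f}")

print(
    "\nThe sigma-0 models score exactly 1.0; scores fall monotonically with "
    "coordinate noise, the augmented variant never exceeds the standard one, "
    "and iLDDT isolates the interface."
)
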