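"""Generate a coherent synthetic study: expression with planted
co-expressed modules, a scale-free interaction network with a dense seed
module, annotations, seeds and an ortholog fixture."""

from pathextend import SyntheticSpec, demo_inputs

spec = SyntheticSpec(n_genes=800, n_samples=40, module_sizes=(20,) * 5,
                     n_decoy_modules=8, decoy_module_size=10, rng_seed=0)
inputs, truth = demo_inputs(spec)

print(f"expression matrix : {inputs.expression.shape[0]} genes x "
      f"{inputs.expression.shape[1]} samples")
print(f"planted modules   : {len(truth['modules'])} "
      f"({sum(len(g) for g in truth['modules'].values())} genes)")
print(f"seed genes        : {len(inputs.seeds)} across "
      f"{len(set(inputs.seeds.subpathway.values()))} sub-pathways")
print(f"reference network : {inputs.ref_net.number_of_nodes()} nodes, "
      f"{inputs.ref_net.number_of_edges()} edges")
print(f"annotated genes   : {len(inputs.annotations)}")
# Every downstream stage has a ground truth: module membership for the
# co-expression network and KNN labels, the planted seed module for the
# scorers, and the ortholog fixture reproduces the network when migrated.
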