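"""Site selection with the modified immune algorithm, checked by enumeration.

On a small instance every p-subset of candidate sites can be enumerated, so
the true optimum of the scalarized four-objective problem is known.  The
immune algorithm should land on exactly that subset.
"""

from rcfopt import MIAParams, oracle_instance, run_mia

instance, p, optimum = oracle_instance(seed=2)
print(f"instance: {instance.n_centers} centers, {instance.n_sites} sites, p = {p}")
print(f"enumerated {optimum.n_enumerated} subsets; "
      f"optimum {optimum.encoding.tolist()} with F = {optimum.F:.6f}")

result = run_mia(instance, MIAParams(p=p, pop_size=30, t_max=200, seed=0))
print(f"MIA best {result.best_encoding.tolist()} with F = {result.best_F:.6f}")
print(f"match: {result.best_encoding.tolist() == optimum.encoding.tolist()}")
print(f"converged at iteration {result.iterations_to_convergence} "
      f"of {len(result.trace)}")
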