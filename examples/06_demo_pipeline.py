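"""The full comparative pipeline on a paired synthetic data set.

Generates a "reactive" species (three extra scheduled salt bridges, smaller
fluctuation amplitudes) and a "non-reactive" species, each as binary and
ternary complexes plus a shared free receptor, then runs every stage:
stability summary, RMSF comparisons, salt-bridge matrices and counts,
pairwise Frobenius distances, and the entropic binding cycle.

Equivalent shell command:  pmhcdyn demo --out demo_out --seed 1
"""

from pmhcdyn.pipeline_cli import build_demo_inputs, run_comparison

config = build_demo_inputs("demo_out", seed=1, n_frames=240)
report = run_comparison(config)

print("counted bridges per species:")
for label, info in report["counts"].items():
    print(f"  {label:22s} {info['n_bridges']:2d} formed / {info['n_candidates']:2d} candidates")

frob = report["frobenius"]["ternary"]
print("\nnormalized Frobenius distance, ternary complexes:")
print(frob.round(2).to_string())

print("\nentropic binding cycle (kJ/mol):")
for group, cyc in report["cycles"].items():
    dd = f", ddG_entropy vs reference = {cyc.delta_delta_binding:+.1f}" \
        if cyc.delta_delta_binding is not None else ""
    print(f"  {group:12s} -T dS_binding = {cyc.binding:8.1f}{dd}")

print(f"\nfull report bundle written under {config.output_dir}/")
print("The reactive species keeps three more formed bridges and, being")
print("stiffer when free, pays a smaller entropic penalty on binding.")
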