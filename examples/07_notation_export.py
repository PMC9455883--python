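"""Symbolic annotations and a DOT diagram for a two-population network.

Annotations name the rule (delta, Omega, p, K_in, ...) and the constraint
flags: A/M allowed, struck-out (or !A/!M in ASCII) prohibited.  The DOT
export encodes roles as node shapes (triangle = excitatory, circle =
inhibitory, hexagon = stimulating device) and rule determinism as edge
style (solid deterministic, dashed probabilistic).
"""

from conngen import NetworkConfig, export_dot, projection_annotation

config = NetworkConfig.model_validate({
    "populations": [
        {"name": "E", "size": 10000, "role": "excitatory"},
        {"name": "I", "size": 2500, "role": "inhibitory"},
        {"name": "E_ext", "size": 10000, "role": "stimulator"},
    ],
    "projections": [
        {"source": "E", "target": "E", "rule": "fixed_in", "k_in": 1000,
         "autapses": False, "multapses": True,
         "weight": {"kind": "constant", "value": 0.1},
         "delay": {"kind": "constant", "value": 1.5}},
        {"source": "E", "target": "I", "rule": "fixed_in", "k_in": 1000,
         "multapses": True},
        {"source": "I", "target": "E", "rule": "fixed_in", "k_in": 250,
         "multapses": True},
        {"source": "I", "target": "I", "rule": "fixed_in", "k_in": 250,
         "autapses": False, "multapses": True},
        {"source": "E_ext", "target": "E", "rule": "one_to_one"},
    ],
    "seed": 1,
})

for k, proj in enumerate(config.projections):
    uni = projection_annotation(proj)
    asc = projection_annotation(proj, ascii_mode=True)
    print(f"{proj.source:>5s} -> {proj.target:<5s}  {uni:24s} ascii: {asc}")

print("\nDOT diagram:\n")
print(export_dot(config, ascii_mode=True))
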