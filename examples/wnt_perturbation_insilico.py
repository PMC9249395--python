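"""In silico Wnt perturbation: which parameter changes mimic treatment?

Searches the activator (act) and inhibitor (inh) axes of the shark
baseline for the minimal relative change that reproduces the phenotypes
seen under pharmacological Wnt manipulation: unicuspid teeth when
signalling is reduced, supernumerary cusps or widened crowns when it is
increased.
"""

from cuspkit.simulator import load_preset
from cuspkit.sweep import SweepSpec, eliminate, mimic_treatment, sweep

base = load_preset("shark")

for direction, reading in (("wnt-down", "reduced Wnt (IWR-like)"),
                           ("wnt-up", "increased Wnt (CHIR-like)")):
    print(f"\n{reading}:")
    for r in mimic_treatment(base, direction):
        if r["category"] == "no-transition":
            print(f"  {r['param']}: no phenotype change within range")
        else:
            print(f"  {r['param']} x{r['multiple']:.1f} -> "
                  f"{r['category']} ({r['n_cusps']} cusps)")

# A one-at-a-time sweep of act, filtered to tricuspid outcomes, shows
# the band of autoactivation values compatible with the wild type.
res = sweep(SweepSpec(base=base, params=["act"], step=0.10,
                      range=(0.5, 1.5)))
tri = eliminate(res, lambda row: row.n_cusps == 3)
lo = tri.accepted["multiple"].min()
hi = tri.accepted["multiple"].max()
print(f"\ntricuspid act band: x{lo:.1f} .. x{hi:.1f} of baseline "
      f"({len(tri.accepted)}/{len(res.grid)} sweep points)")
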