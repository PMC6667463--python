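"""Predict a mixture's relaxivity signature and invert it back to fractions.

The forward model sums pure-component MTV dependencies weighted by their
fractions; the inverse solves the least-squares system on the simplex.
"""

from mdmtv import ComponentLibrary, MixtureDesign, predict_mixture_dependency, unmix

library = ComponentLibrary(
    {
        "PtdCho": {"R1": (1.2, 0.30), "MTsat": (4.0, -0.05), "R2": (18.0, 3.5)},
        "PS": {"R1": (3.0, 0.28), "MTsat": (11.0, -0.15), "R2": (40.0, 4.0)},
        "Spg": {"R1": (2.1, 0.32), "MTsat": (16.0, -0.25), "R2": (28.0, 4.5)},
    }
)
truth = MixtureDesign({"PtdCho": 0.25, "PS": 0.25, "Spg": 0.5})

signature = predict_mixture_dependency(library, truth)
print("predicted mixture slopes:",
      {p: round(d.slope, 3) for p, d in signature.fits.items()})

estimate, residual, diag = unmix(signature, library, constraints="NONNEG_SUM_TO_ONE")
print("recovered fractions:    ",
      {k: round(v, 6) for k, v in estimate.fractions.items()})
print(f"residual norm: {residual:.2e}   condition number: {diag['condition_number']:.1f}")

print()
print("With a full-rank component library the designed fractions are")
print("recovered exactly; the residual is numerical zero.")
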