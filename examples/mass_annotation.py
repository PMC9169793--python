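"""Exact-mass annotation of a putative flavonoid pathway product.

Computes the monoisotopic [M+H]+ m/z of an O-methylated flavonoid
composition and the ppm deviation of an observed ion, the arithmetic used
to support an elemental-composition call from LC-MS data.
"""

from bgcscout.massannot import monoisotopic_mz, parse_formula, ppm_error

formula = parse_formula("C18H16O6")
for adduct in ("M", "[M+H]+", "[M-H]-", "[M+H-H2O]+"):
    print(f"{adduct:<12} {monoisotopic_mz(formula, adduct):.4f}")

observed = 329.1010
theoretical = monoisotopic_mz(formula, "[M+H]+")
print(f"observed {observed} vs theoretical {theoretical:.4f}: "
      f"{ppm_error(observed, theoretical):+.2f} ppm")
# A |ppm| of a few parts per million is the usual bar for accepting an
# elemental composition from high-resolution MS.
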