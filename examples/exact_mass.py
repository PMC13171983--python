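"""Exact-mass arithmetic: from a chemical formula to targeted m/z values.

Parses an unlabeled and a uniformly 13C-labeled formula, computes their
neutral monoisotopic masses and the singly protonated/deprotonated m/z
that the targeted extraction searches for at +/- 5 ppm.
"""

from ccmscan import adduct_mz, monoisotopic_mass, parse_formula, ppm_error

for label, text in [("glutamine", "C5H10N2O3"),
                    ("U-13C glucose-6-phosphate (IS)", "13C6H13O9P")]:
    f = parse_formula(text)
    m = monoisotopic_mass(f)
    print(f"{label:32s} {f.format():18s} neutral {m:10.5f} Da"
          f"  [M+H]+ {adduct_mz(m, '[M+H]+'):10.5f}"
          f"  [M-H]- {adduct_mz(m, '[M-H]-'):10.5f}")

# How selective is a 5 ppm gate at m/z 147?  An ion 1.6 mDa away:
theo = adduct_mz(monoisotopic_mass(parse_formula("C5H10N2O3")), "[M+H]+")
print(f"\nppm error of 147.07800 vs glutamine [M+H]+: "
      f"{ppm_error(147.07800, theo):+.2f} ppm (outside a 5 ppm gate)")
# The labeled IS sits ~5 Da above its unlabeled analyte: the mass shift of
# five 13C substitutions, which is what makes isotope dilution possible.
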