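"""Dereplication arithmetic: CHO formula candidates for observed ions.

Enumerates all C/H/O molecular formulas whose chosen adduct lies within a
ppm window of an observed m/z, ranked by mass accuracy — the accurate-mass
step used to putatively identify PLS-DA biomarkers.
"""

from litterlab.annotation import enumerate_cho_formulas

ions = [
    (615.0987, "[M-H]-"),    # a galloylated flavonol glycoside
    (341.1086, "[M-H]-"),    # a disaccharide
    (387.1143, "[M+HCOO]-"),  # the same disaccharide as its formate adduct
]

for observed, adduct in ions:
    candidates = enumerate_cho_formulas(observed, adduct, tol_ppm=5)
    print(f"\nm/z {observed} as {adduct}: {len(candidates)} candidate(s)")
    for cand in candidates[:5]:
        print(f"  {str(cand.formula):12s} theo {cand.theoretical_mz:.5f}  "
              f"{cand.ppm:+.2f} ppm  RDBE {cand.rdbe:.0f}")

print("\nThe top-ranked formulas (C28H24O16, C12H22O11) match the published "
      "biomarker assignments; sub-ppm errors indicate the adduct arithmetic "
      "and the instrument calibration agree.")
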