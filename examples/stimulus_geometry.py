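"""Build the DEM stimulus layouts and print the photometric/angular facts.

The numbers printed here characterize the digitized test: optotype size in
logMAR, Michelson contrast of the digits against the background, and the
visual angles of the layout spacings at the 65 cm viewing distance.
"""

from demgaze import build_layout, logmar_of_optotype, michelson_contrast, mm_to_deg

layout_c = build_layout("C")
layout_a = build_layout("A")

print(f"subtest C: {layout_c.n_positions} numbers in {layout_c.n_rows} rows, "
      f"row extent {layout_c.row_extent_mm} mm = {mm_to_deg(layout_c.row_extent_mm, 650):.1f} deg")
print(f"subtest A: {layout_a.n_positions} numbers in 2 columns, "
      f"column gap {layout_a.row_extent_mm} mm = {mm_to_deg(layout_a.row_extent_mm, 650):.1f} deg")
print(f"vertical number spacing: 14.6 mm = {mm_to_deg(14.6, 650):.2f} deg")
print(f"optotype: 4.9 mm at 650 mm -> logMAR {logmar_of_optotype(4.9, 650):.2f}")
print(f"contrast: Lmax 235.6, Lmin 2.1 cd/m2 -> {michelson_contrast(235.6, 2.1):.1%} Michelson")
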