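"""Clonogenic survival from a colony-count table.

Plates with fewer than 50 or more than 300 colonies are discounted;
surviving fractions are mean plating-efficiency ratios against the
appropriate unirradiated reference, with 2 sd/√n error bars.
"""

from mrtbio import PlateRecord, survival_table

plates = []
for i, c in enumerate((190, 210, 205, 195, 188, 202)):
    plates.append(PlateRecord(f"c{i}", "control", 0.0, 400, c))
for i, c in enumerate((170, 182, 165, 174, 180, 169)):
    plates.append(PlateRecord(f"m0{i}", "mrt", 0.0, 400, c))
for i, c in enumerate((88, 95, 79, 90, 84, 93)):
    plates.append(PlateRecord(f"m5{i}", "mrt", 5.0, 400, c))
plates.append(PlateRecord("bad", "mrt", 5.0, 400, 34))  # < 50 colonies: dropped

table = survival_table(plates)
print(table.round(3).to_string(index=False))
# The 0 Gy "mrt" point is referenced to the cell-only control; the 5 Gy
# point to the same treatment's 0 Gy plates, so it reads the pure
# radiation effect (~0.5 here).
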