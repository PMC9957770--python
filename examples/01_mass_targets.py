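"""Derive oxime-conjugate m/z targets for an aminotransferase screen.

Each amino donor is deaminated in silico (-NH3, +O) to its keto acid,
which the aminooxy probe tags with a fixed m/z contribution of 793.2365
minus one water.  The printed table is the instrument target list.
"""

from oximsi import ProbeSpec, build_target_panel, default_panel
from oximsi.chem import targets_to_frame

panel = default_panel()
donors = [panel[name] for name in ("Leu", "Trp", "His", "Glu", "Ala")]
acceptors = [panel["alpha-KG"]]

targets = build_target_panel(donors, acceptors, ProbeSpec())
table = targets_to_frame(targets)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

# The Leu / Trp / His product conjugates are the three browsable display
# channels of the assay (905.3, 978.3, 929.3 after rounding to one
# decimal).  The Glu row carries a degenerate-pair warning: glutamate's
# transamination product IS alpha-ketoglutarate, so in a Glu + alpha-KG
# well the conversion ratio is unidentifiable.
for name in ("Leu>Leu-keto", "Trp>Trp-keto", "His>His-keto"):
    mz = float(table.set_index("name").loc[name, "conjugate_mz"])
    print(f"{name:>14}: display channel {mz:.1f}")
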