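"""Named locus panels for the NW Anatolian lynx microsatellite study design.

The field panel is 14 autosomal loci plus two sexing loci (amelogenin and
zinc-finger).  Derived panels used by the analyses:

* ``RETAINED_11`` — FCA441 and F115 dropped (null alleles, HWE departure),
  FCA478 dropped (monomorphic).
* ``SHARED_10``  — the loci shared with earlier European lynx datasets,
  used for cross-population comparison.
* ``COMPARE_8``  — the loci with complete genotypes across enough samples
  for the invasive vs. non-invasive subsampling comparison.
"""

from .genodata import Locus

AUTOSOMAL_14 = [
    "FCA006", "FCA008", "FCA082", "FCA097", "FCA105", "FCA229", "FCA441",
    "FCA478", "FCA506", "FCA718", "FCA1023", "F115", "LCA109", "LCA110",
]

SEXING = ["F-AMEL", "Z-Zf"]

RETAINED_11 = [
    "FCA006", "FCA008", "FCA082", "FCA097", "FCA105", "FCA229",
    "FCA506", "FCA718", "FCA1023", "LCA109", "LCA110",
]

SHARED_10 = [
    "FCA006", "FCA008", "FCA082", "FCA097", "FCA105", "FCA229",
    "FCA506", "FCA718", "FCA1023", "LCA110",
]

COMPARE_8 = [
    "FCA008", "FCA082", "FCA097", "FCA105", "FCA229", "FCA1023",
    "LCA109", "LCA110",
]

PANELS = {
    "full": AUTOSOMAL_14,
    "retained11": RETAINED_11,
    "shared10": SHARED_10,
    "compare8": COMPARE_8,
}


def field_panel() -> list[Locus]:
    """The full 16-locus field panel (14 autosomal + 2 sexing)."""
    return ([Locus(name=n, kind="autosomal") for n in AUTOSOMAL_14]
            + [Locus(name=n, kind="sexing") for n in SEXING])
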