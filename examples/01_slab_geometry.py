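"""Depth geometry of the six slab-construction schemes.

Prints, for every scheme, the depth band(s) it averages and their
boundaries in micrometres below the inner limiting membrane (ILM).  The
numbers are the published instrument geometry: 50 axial pixels of
3.87 um, i.e. the first 193.5 um of retina below the ILM.
"""

from smas.depth import scheme_catalog, smas_band

catalog = scheme_catalog()

print("SMAS: twelve 4-pixel slabs (first 7 analysed)")
for m in range(1, 13):
    band = smas_band(m)
    lo, hi = band.depth_range_um()
    tag = " *" if m <= catalog["SMAS"].analyzed_slabs else ""
    print(f"  slab {m:2d}: pixels {band.pixel_start:2d}-{band.pixel_end:2d}"
          f"  {lo:6.1f} - {hi:6.1f} um{tag}")

for name in ("Hood", "Ashimatey", "BestVis", "AllVis", "Deep"):
    scheme = catalog[name]
    print(f"\n{name}:")
    seen = set()
    for region, band in scheme.bands.items():
        if band in seen:
            continue
        seen.add(band)
        lo, hi = band.depth_range_um()
        regions = [r for r, b in scheme.bands.items() if b == band]
        print(f"  pixels {band.pixel_start:2d}-{band.pixel_end:2d}"
              f"  {lo:6.1f} - {hi:6.1f} um   ({', '.join(regions)})")

# An asterisk marks the SMAS slabs that enter detection (down to 116.1 um);
# region-dependent schemes average different depths in different retinal
# regions, which is why their boundaries are listed per region.
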