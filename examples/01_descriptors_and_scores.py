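"""Descriptor panel and brain-penetration scores for the built-in fixtures.

Builds the HR-series fixture panel, computes the full physicochemical panel
(MW, TPSA, ClogP/ClogD, ESOL logS, Miller polarizability, minimal projection
area) and the CNS-MPO / BBB scores, and prints one line per compound.
"""

from bpascreen import MpaConfig, builtin_fixture, full_descriptors, score_descriptors

# a lighter MPA search than the default keeps this demo quick
mpa_cfg = MpaConfig(n_conformers=5, orientation_grid=12.0, raster_resolution=0.12, refine=False)

print(f"{'id':6} {'MW':>6} {'TPSA':>5} {'ClogD':>6} {'-logS':>6} {'PL':>5} {'MPA':>5} "
      f"{'CNS-MPO':>8} {'BBB':>5}")
for compound in builtin_fixture("hr_named"):
    ds = full_descriptors(compound, mpa_config=mpa_cfg)
    s = score_descriptors(ds)
    print(
        f"{compound.id:6} {ds.mw:6.1f} {ds.tpsa:5.1f} {ds.clogd_74:6.2f} "
        f"{ds.neg_logs:6.2f} {ds.polarizability:5.1f} {ds.mpa:5.1f} "
        f"{s.cns_mpo:8.2f} {s.bbb_score:5.2f}"
    )

print(
    "\nCNS-MPO >= 4 and BBB score in [4, 5] are the conventional CNS-favorable"
    "\nbands; MPA < 60 A^2 indicates passive diffusion across the BBB is"
    "\ngeometrically plausible; PL in 40-50 A^3 is typical for this series."
)
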