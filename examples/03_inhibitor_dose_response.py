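"""Classical vs substrate-selective inhibitors, single vs dual assay.

A 'substrate-selective' compound binds the p38-MK2 complex with K_I = 1 nM
and everything else with K_I/(1-f) = 100 nM (f = 0.99); a classical
compound binds every p38 form at 1 nM.  In the single-substrate assays the
selective compound is ~7-fold more potent against pMK2 than pATF2 — but in
the dual assay, with [MK2] = 10 nM > [p38] = 0.5 nM, mass action drives
all enzyme into the p38:MK2:inhibitor complex and the ATF2 IC50 collapses
onto the MK2 IC50: selectivity is lost.

The literature kcat_MK2 (0.17 1/s) is used so the 30-min MK2 readout
stays in the assay's linear range.
"""

import p38compete as pc

params = pc.KineticParameters(kcat_mk2=pc.LITERATURE_KCAT_MK2)
compounds = {
    "classical": pc.InhibitorSpec(ki=1.0, inhibitor_class="classical"),
    "selective": pc.InhibitorSpec(ki=1.0, selectivity_f=0.99,
                                  inhibitor_class="substrate_selective"),
}

ic50 = {}
for cname, spec in compounds.items():
    for pname, proto in (("single_atf2", pc.AssayProtocol.single_atf2()),
                         ("single_mk2", pc.AssayProtocol.single_mk2()),
                         ("dual", pc.AssayProtocol.dual())):
        for sp, dr in pc.run_assay(proto, params, "base", spec).items():
            fit = pc.fit_hill(dr.doses, dr.normalized)
            ic50[(cname, pname, sp)] = fit.ic50_or_raise()

for cname in compounds:
    sa = ic50[(cname, "single_atf2", "pATF2")]
    sm = ic50[(cname, "single_mk2", "pMK2")]
    da = ic50[(cname, "dual", "pATF2")]
    dm = ic50[(cname, "dual", "pMK2")]
    print(f"{cname}:")
    print(f"  IC50 single: pATF2 {sa:7.2f} nM   pMK2 {sm:6.2f} nM   "
          f"selectivity {sa/sm:5.2f}")
    print(f"  IC50 dual:   pATF2 {da:7.2f} nM   pMK2 {dm:6.2f} nM   "
          f"selectivity {da/dm:5.2f}")
    print(f"  ATF2 left-shift single->dual: {pc.shift_factor(sa, da):.2f}x,"
          f"  pMK2 IC50 change: {abs(dm/sm-1)*100:.1f}%")

print("\nSelectivity = IC50_ATF2/IC50_MK2; its collapse toward 1 in the"
      " dual assay is the sequestration effect ([MK2] > [active p38]).")
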