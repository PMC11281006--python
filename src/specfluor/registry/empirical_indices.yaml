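# Published empirical spectral indices, as expressions over reflectance
# bands R<wavelength nm>.  This file is configuration, not code: edit an
# entry to match a different published definition and the evaluation
# panel will pick it up.
#
# PRI, ARI2, CRI1, CRI2, EVI, PSRI and RGI follow the widely used
# literature forms.  RSI, OCAR and YCAR circulate in several variants;
# the simple ratio forms below are editable placeholders and should be
# checked against the source publication before quantitative use.
PRI: "(R531 - R570) / (R531 + R570)"
ARI2: "R800 * (1 / R550 - 1 / R700)"
CRI1: "1 / R510 - 1 / R550"
CRI2: "1 / R510 - 1 / R700"
EVI: "2.5 * (R800 - R670) / (R800 + 6 * R670 - 7.5 * R475 + 1)"
PSRI: "(R680 - R500) / R750"
RGI: "R690 / R550"
RSI: "R810 / R660"
OCAR: "R630 / R680"
YCAR: "R600 / R680"
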