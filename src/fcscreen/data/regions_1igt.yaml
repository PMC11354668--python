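# Default antibody region map for 1IGT-style chain naming.
#   A, C : light chains  (VL, CL)
#   B, D : heavy chains  (VH, CH1, CH2, CH3, hinge)
#   E, F : glycan chains (typed by residue name; no intervals needed)
#
# Author numbering throughout.  Published descriptions of the Fc span for
# this receptor are internally inconsistent (one source gives ~230-444,
# another 242-474 with a hinge at 455-475); this default uses the 242-474
# window split at 353/354 into CH2/CH3 with the hinge at 455-475.
# Override with --regions for any other receptor or convention.
regions:
  - {chain: A, start: 1, end: 108, region: VL}
  - {chain: A, start: 109, end: 214, region: CL}
  - {chain: C, start: 1, end: 108, region: VL}
  - {chain: C, start: 109, end: 214, region: CL}
  - {chain: B, start: 1, end: 120, region: VH}
  - {chain: B, start: 121, end: 241, region: CH1}
  - {chain: B, start: 242, end: 353, region: CH2}
  - {chain: B, start: 354, end: 454, region: CH3}
  - {chain: B, start: 455, end: 475, region: hinge}
  - {chain: D, start: 1, end: 120, region: VH}
  - {chain: D, start: 121, end: 241, region: CH1}
  - {chain: D, start: 242, end: 353, region: CH2}
  - {chain: D, start: 354, end: 454, region: CH3}
  - {chain: D, start: 455, end: 475, region: hinge}
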