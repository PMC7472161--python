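# Default 32-channel Biosemi/10-20 montage: 4 midline channels + 14
# left-right pairs, in the acquisition order of the emotion database's
# recording hardware.  Custom montages follow the same schema.
midline: [Fz, Cz, Pz, Oz]
pairs:
  - [Fp1, Fp2]
  - [AF3, AF4]
  - [F7, F8]
  - [F3, F4]
  - [FC5, FC6]
  - [FC1, FC2]
  - [T7, T8]
  - [C3, C4]
  - [CP5, CP6]
  - [CP1, CP2]
  - [P7, P8]
  - [P3, P4]
  - [PO3, PO4]
  - [O1, O2]
acquisition_order:
  [Fp1, AF3, F3, F7, FC5, FC1, C3, T7, CP5, CP1,
   P3, P7, PO3, O1, Oz, Pz, Fp2, AF4, Fz, F4,
   F8, FC6, FC2, Cz, C4, T8, CP6, CP2, P4, P8,
   PO4, O2]
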