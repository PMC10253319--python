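# Template config for the monitored protein-DNA interface distances.
#
# 25 definitions in total, matching the dimensionality of the SOM training
# matrix. The first four are the named ARNT bHLH salt bridges (R88, R91 and
# R101 to DNA phosphate groups, plus the intramolecular R101-E98 bridge);
# the remaining 21 are PLACEHOLDER slots: chain ids and residue/nucleotide
# numbers below are illustrative and MUST be replaced with the pairings of
# your own structure before use on real data.
#
# Endpoint modes: "centroid" (charged-group centroid: Arg NH1+NH2+NE,
# Lys NZ, Glu OE1+OE2, Asp OD1+OD2), "phosphate" (DNA backbone P atom),
# "atom" (explicit atom_name).
#
# Chain convention used by the placeholders: A = AhR, B = ARNT,
# C/D = DNA strands.
distances:
  - name: ARNT_R88-DNA_P
    a: {chain: B, res_id: 88, mode: centroid}
    b: {chain: C, res_id: 7, mode: phosphate}
  - name: ARNT_R91-DNA_P
    a: {chain: B, res_id: 91, mode: centroid}
    b: {chain: C, res_id: 8, mode: phosphate}
  - name: ARNT_R101-DNA_P
    a: {chain: B, res_id: 101, mode: centroid}
    b: {chain: C, res_id: 9, mode: phosphate}
  - name: ARNT_R101-ARNT_E98
    a: {chain: B, res_id: 101, mode: centroid}
    b: {chain: B, res_id: 98, mode: centroid}
  - name: slot_05
    a: {chain: A, res_id: 39, mode: centroid}
    b: {chain: C, res_id: 5, mode: phosphate}
  - name: slot_06
    a: {chain: A, res_id: 42, mode: centroid}
    b: {chain: C, res_id: 6, mode: phosphate}
  - name: slot_07
    a: {chain: A, res_id: 46, mode: centroid}
    b: {chain: D, res_id: 5, mode: phosphate}
  - name: slot_08
    a: {chain: A, res_id: 49, mode: centroid}
    b: {chain: D, res_id: 6, mode: phosphate}
  - name: slot_09
    a: {chain: A, res_id: 53, mode: centroid}
    b: {chain: D, res_id: 7, mode: phosphate}
  - name: slot_10
    a: {chain: B, res_id: 86, mode: centroid}
    b: {chain: D, res_id: 8, mode: phosphate}
  - name: slot_11
    a: {chain: B, res_id: 94, mode: centroid}
    b: {chain: D, res_id: 9, mode: phosphate}
  - name: slot_12
    a: {chain: B, res_id: 98, mode: centroid}
    b: {chain: C, res_id: 10, mode: phosphate}
  - name: slot_13
    a: {chain: B, res_id: 102, mode: centroid}
    b: {chain: C, res_id: 11, mode: phosphate}
  - name: slot_14
    a: {chain: B, res_id: 105, mode: centroid}
    b: {chain: D, res_id: 10, mode: phosphate}
  - name: slot_15
    a: {chain: A, res_id: 36, mode: centroid}
    b: {chain: A, res_id: 40, mode: centroid}
  - name: slot_16
    a: {chain: A, res_id: 44, mode: centroid}
    b: {chain: C, res_id: 12, mode: phosphate}
  - name: slot_17
    a: {chain: A, res_id: 47, mode: centroid}
    b: {chain: C, res_id: 13, mode: phosphate}
  - name: slot_18
    a: {chain: A, res_id: 51, mode: centroid}
    b: {chain: D, res_id: 11, mode: phosphate}
  - name: slot_19
    a: {chain: B, res_id: 89, mode: centroid}
    b: {chain: D, res_id: 12, mode: phosphate}
  - name: slot_20
    a: {chain: B, res_id: 92, mode: centroid}
    b: {chain: D, res_id: 13, mode: phosphate}
  - name: slot_21
    a: {chain: B, res_id: 96, mode: centroid}
    b: {chain: C, res_id: 14, mode: phosphate}
  - name: slot_22
    a: {chain: B, res_id: 99, mode: centroid}
    b: {chain: C, res_id: 15, mode: phosphate}
  - name: slot_23
    a: {chain: B, res_id: 103, mode: centroid}
    b: {chain: D, res_id: 14, mode: phosphate}
  - name: slot_24
    a: {chain: A, res_id: 38, mode: centroid}
    b: {chain: D, res_id: 15, mode: phosphate}
  - name: slot_25
    a: {chain: B, res_id: 87, mode: centroid}
    b: {chain: B, res_id: 95, mode: centroid}
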