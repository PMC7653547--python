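# Default descriptor roster for a GFP chromophore-pocket analysis.
#
# This is a template keyed to 1EMA-style residue numbering with the
# chromophore as residue CRO 66.  Residue ids — in particular the id of the
# proton-wire crystallographic water (here 301) and which Glu222
# carboxylate oxygen accepts the H-bond (here OE2) — MUST be checked
# against the actual topology before use: PDB water numbering and OE1/OE2
# assignment are not portable between structures.
#
# Units: distances Å, angles/torsions degrees.

descriptors:
  # proton-wire heavy-atom distances
  - name: "O(Tyr66)-O(Wat)"
    kind: distance
    atoms: [[CRO, 66, OH], [HOH, 301, O]]
  - name: "O(Wat)-O(Ser205)"
    kind: distance
    atoms: [[HOH, 301, O], [SER, 205, OG]]
  - name: "O(Ser205)-O(Glu222)"
    kind: distance
    atoms: [[SER, 205, OG], [GLU, 222, OE2]]
  # H-bonds flanking the chromophore phenol
  - name: "N(His148)-O(Wat)"
    kind: distance
    atoms: [[HIS, 148, ND1], [HOH, 301, O]]
  - name: "N(His148)-O(Tyr66)"
    kind: distance
    atoms: [[HIS, 148, ND1], [CRO, 66, OH]]
  - name: "O(Asn146)-O(Tyr66)"
    kind: distance
    atoms: [[ASN, 146, OD1], [CRO, 66, OH]]
  - name: "O(Thr203)-O(Wat)"
    kind: distance
    atoms: [[THR, 203, OG1], [HOH, 301, O]]
  # imidazolinone-side H-bonds
  - name: "O(Imid)-N(Arg96)"
    kind: distance
    atoms: [[CRO, 66, O2], [ARG, 96, NH1]]
  - name: "O(Imid)-N2(Arg96)"
    kind: distance
    atoms: [[CRO, 66, O2], [ARG, 96, NH2]]
  - name: "O(Imid)-N(Gln94)"
    kind: distance
    atoms: [[CRO, 66, O2], [GLN, 94, NE2]]
  # chromophore-bridge internal coordinates
  - name: "CCC(omega)"
    kind: angle
    atoms: [[CRO, 66, CD2], [CRO, 66, CB2], [CRO, 66, CA2]]
  - name: "proton-wire dihedral"
    kind: dihedral
    atoms: [[CRO, 66, OH], [HOH, 301, O], [SER, 205, OG], [GLU, 222, OE2]]

# Pocket selection for the cavity volume: chromophore + Ser65 (fused into
# CRO in mature GFP structures) + Ser205 + Glu222 + proton-wire water.
# List every heavy atom (and hydrogens, if present in the topology) of
# those residues for the actual structure in use; in the reference study
# this region counts 44 atoms.
selection_note: >
  Fill 'selection' with [residue_name, residue_id, atom_name] triples
  covering the pocket; see README for a worked example.
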