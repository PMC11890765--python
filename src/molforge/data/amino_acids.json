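{
  "_comment": "22 proteinogenic amino acids. Atom maps: 1 = backbone amine N, 2 = backbone carboxyl C, 3 = carboxyl hydroxyl O (removed on condensation), 4 = thiol/selenol chalcogen (disulfide bridging, cysteine only).",
  "Ala": "[NH2:1][C@@H](C)[C:2](=O)[OH:3]",
  "Arg": "[NH2:1][C@@H](CCCNC(=N)N)[C:2](=O)[OH:3]",
  "Asn": "[NH2:1][C@@H](CC(N)=O)[C:2](=O)[OH:3]",
  "Asp": "[NH2:1][C@@H](CC(=O)O)[C:2](=O)[OH:3]",
  "Cys": "[NH2:1][C@@H](C[SH:4])[C:2](=O)[OH:3]",
  "Gln": "[NH2:1][C@@H](CCC(N)=O)[C:2](=O)[OH:3]",
  "Glu": "[NH2:1][C@@H](CCC(=O)O)[C:2](=O)[OH:3]",
  "Gly": "[NH2:1]C[C:2](=O)[OH:3]",
  "His": "[NH2:1][C@@H](Cc1c[nH]cn1)[C:2](=O)[OH:3]",
  "Ile": "[NH2:1][C@@H]([C@@H](C)CC)[C:2](=O)[OH:3]",
  "Leu": "[NH2:1][C@@H](CC(C)C)[C:2](=O)[OH:3]",
  "Lys": "[NH2:1][C@@H](CCCCN)[C:2](=O)[OH:3]",
  "Met": "[NH2:1][C@@H](CCSC)[C:2](=O)[OH:3]",
  "Phe": "[NH2:1][C@@H](Cc1ccccc1)[C:2](=O)[OH:3]",
  "Pro": "[NH:1]1CCC[C@H]1[C:2](=O)[OH:3]",
  "Pyl": "[NH2:1][C@@H](CCCCNC(=O)[C@@H]1CCC=N1)[C:2](=O)[OH:3]",
  "Sec": "[NH2:1][C@@H](C[SeH:4])[C:2](=O)[OH:3]",
  "Ser": "[NH2:1][C@@H](CO)[C:2](=O)[OH:3]",
  "Thr": "[NH2:1][C@@H]([C@H](C)O)[C:2](=O)[OH:3]",
  "Trp": "[NH2:1][C@@H](Cc1c[nH]c2ccccc12)[C:2](=O)[OH:3]",
  "Tyr": "[NH2:1][C@@H](Cc1ccc(O)cc1)[C:2](=O)[OH:3]",
  "Val": "[NH2:1][C@@H](C(C)C)[C:2](=O)[OH:3]"
}
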