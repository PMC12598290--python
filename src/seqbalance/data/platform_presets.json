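{
  "version": 1,
  "comment": "Platform/protocol presets used across the 100K WGS project. clusters_per_flowcell is the stated 3.0e8 reads/flow cell for the HiSeq 2500 Rapid Run; for the other rows it is back-computed from the printed per-flow-cell yield label as yield_bp / (2 x read_length).",
  "presets": [
    {"id": "hiseq2500-162pe", "name": "HiSeq 2500", "mode": "Rapid Run", "read_length_bp": 162, "paired": true, "clusters_per_flowcell": 3.0e8, "flowcells_per_run": 2, "yield_label": "97Gb x 2"},
    {"id": "hiseq2500-259pe", "name": "HiSeq 2500", "mode": "Rapid Run", "read_length_bp": 259, "paired": true, "clusters_per_flowcell": 3.0e8, "flowcells_per_run": 2, "yield_label": "155Gb x 2"},
    {"id": "hiseqx-150pe", "name": "HiSeq X", "mode": "", "read_length_bp": 150, "paired": true, "clusters_per_flowcell": 3.0e9, "flowcells_per_run": 2, "yield_label": "900Gb x 2"},
    {"id": "dnbseq-g400-150pe", "name": "DNBSEQ-G400", "mode": "FCL", "read_length_bp": 150, "paired": true, "clusters_per_flowcell": 1.8e9, "flowcells_per_run": 2, "yield_label": "540Gb x 2"},
    {"id": "dnbseq-t7-150pe", "name": "DNBSEQ-T7", "mode": "", "read_length_bp": 150, "paired": true, "clusters_per_flowcell": 5.0e9, "flowcells_per_run": 4, "yield_label": "1.5Tb x 4"},
    {"id": "novaseq6000-150pe", "name": "NovaSeq 6000", "mode": "S4 flowcell", "read_length_bp": 150, "paired": true, "clusters_per_flowcell": 1.0e10, "flowcells_per_run": 2, "yield_label": "3Tb x 2"},
    {"id": "novaseq6000-151pe", "name": "NovaSeq 6000", "mode": "S4 flowcell", "read_length_bp": 151, "paired": true, "clusters_per_flowcell": 9.9337748344e9, "flowcells_per_run": 2, "yield_label": "3Tb x 2"},
    {"id": "novaseq6000-161pe", "name": "NovaSeq 6000", "mode": "S4 flowcell", "read_length_bp": 161, "paired": true, "clusters_per_flowcell": 9.9378881988e9, "flowcells_per_run": 2, "yield_label": "3.2Tb x 2"},
    {"id": "novaseqxplus-10b-161pe", "name": "NovaSeq X Plus", "mode": "10B flowcell", "read_length_bp": 161, "paired": true, "clusters_per_flowcell": 9.3167701863e9, "flowcells_per_run": 2, "yield_label": "3Tb x 2"},
    {"id": "novaseqxplus-25b-161pe", "name": "NovaSeq X Plus", "mode": "25B flowcell", "read_length_bp": 161, "paired": true, "clusters_per_flowcell": 2.4844720497e10, "flowcells_per_run": 2, "yield_label": "8Tb x 2"}
  ]
}
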