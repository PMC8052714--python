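- type_id: R1
  modulator_domain: cytokine
  source_domain: cell
  target_domain: cytokine
  same_cell_constraint: none
  notes: cytokine-modulated cell source driving a cytokine
- type_id: R2
  modulator_domain: cell
  source_domain: cell
  target_domain: cytokine
  same_cell_constraint: none
  notes: cell-modulated cell source driving a cytokine; the modulator cell may differ
    from the source cell because the target is a cytokine
- type_id: R3
  modulator_domain: cell_or_none
  source_domain: cytokine
  target_domain: cell
  same_cell_constraint: all_cell_roles_same
  notes: a cytokine drives a cell, modulated by that same cell (feedback) or unmodulated
    (n.a.)
- type_id: R4
  modulator_domain: cytokine_or_none
  source_domain: cell
  target_domain: cell
  same_cell_constraint: all_cell_roles_same
  notes: autocrine self-action of a cell, cytokine-modulated or unmodulated (n.a.)
- type_id: R5
  modulator_domain: none
  source_domain: cell
  target_domain: cytokine
  same_cell_constraint: none
  notes: unmodulated cell source driving a cytokine
- type_id: R6
  modulator_domain: none
  source_domain: cell
  target_domain: cell
  same_cell_constraint: none
  notes: unmodulated cell source driving a cell
- type_id: R7
  modulator_domain: cell
  source_domain: cell
  target_domain: cell
  same_cell_constraint: all_cell_roles_same
  notes: 'fully autocrine loop: a cell modulates its own self-action'
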