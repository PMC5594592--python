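/root/pkg/analysis_shared.py06_fermentation_rates.py05_design_constructs.py04_apply_deletions.py01_simulate_inputs.py02_classify_genes.py03_select_regions.py   �   ���� !n�!~������         �   �����⟑h�n �����         �   �����ۯPB������         �   K���@JI��V�����         �   ���{�D�w��������                                         �   ����%o�k��?������         �   ����qu���{�����         }�)G1z}�)G1z��������������� �   @�������      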