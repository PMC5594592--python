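/root/pkg/testsconftest.pytest_alignment.pytest_fermentation.py__init__.pytest_genome_model.pytest_constructs.pytest_acceptance.pyoracles.pytest_classification.pytest_ledger.pytest_synthetic.pytest_regions.pytest_pipeline.py�   ������x�={H֫����         �   ����K��i?ȧ�����         �   ����	�LM�o̫����         �   b���a�*��[m�����         �   ,���%v�*���-�����         �   ���}�ù^tY������          �   �����'�[�«����         �   �����k��5�
�����         �   j����(�j
�_L�����                                         �   ���Z�>)#|�����         �   ������O�Ԯ�����         �   ����#5F��{�����         �   ����a�*��[m�����         S<67�Pcyn#	PS<67�Pcyn#	P��� �   @�������      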