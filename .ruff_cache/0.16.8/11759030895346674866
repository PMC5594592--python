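/root/pkg/src/genreduceledger.pyconstructs.pyregions.pyalignment.pysimulate.pyfermentation.pypipeline.pyclassify.py__init__.pypublished.pygenome_model.py       �   ����G+T�۫����         �   ����� �����v�����         �   ����枂��:0�����         �   h������OK�l�����                                         �   ���������������         �   �����*ۄ���P�����         cli.py���vVoK������         �   ����e���p\�����         �   w���G+T�۫����         �   M���a�*��[m�����         �    ���T��F���i�����         �   ����a�*��[m�����         "`*:A�L7m6"`*:A�L7m6����� �   ��������      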