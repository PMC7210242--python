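histology,device_reading
IC on ink,+
IDC on ink,+
IDC < 1 mm from ink,+
"IDC < 1 mm from ink, DCIS on ink",+
IDC > 2 mm from ink,+
IDC > 2 mm from ink,-
DCIS < 2 mm from ink,+
DCIS < 2 mm from ink,-
DCIS > 2 mm from ink,-
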