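surface_histology,device_reading,tumor_found,reexcision_histology,footnote_a
DCIS < 2 mm from ink,+,+,DCIS,False
DCIS < 2 mm from ink,+,-,Benign,False
DCIS < 2 mm from ink,+,+,DCIS,True
IDC on ink,+,+,IDC,True
ILC on ink,+,+,ILC,True
DCIS < 2 mm from ink,+,-,Benign,True
IDC on ink,-,-,Benign,True
DCIS < 2 mm from ink,-,-,Benign,True
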