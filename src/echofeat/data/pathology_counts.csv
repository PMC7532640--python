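group,pathology,count
benign,Adenosis,67
benign,Benign phyllodes tumour,6
benign,Fibroadenoma,68
benign,Inflammation,8
benign,Intraductal papilloma,20
benign,Complex cyst,5
malignant,Intraductal carcinoma in situ,12
malignant,Intraductal papillary carcinoma,2
malignant,Invasive ductal carcinoma,18
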