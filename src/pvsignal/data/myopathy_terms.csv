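pt_name,meddra_code,scope
rhabdomyolysis,10039020,narrow
myopathy,10028641,narrow
toxic myopathy,10062917,narrow
necrotising myositis,10078091,narrow
necrotizing myositis,10078091,narrow
muscle necrosis,10052904,narrow
myoglobinuria,10028629,narrow
myoglobin blood increased,10028625,narrow
myoglobin blood present,10028626,narrow
myoglobin urine present,10028634,narrow
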