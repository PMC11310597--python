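# Verbatim-pattern -> canonical ingredient mapping, one pair per line,
# tab-separated. Patterns are matched after cleaning (uppercase, punctuation
# to spaces, dose/formulation/salt tokens removed, whitespace collapsed).
# Users may extend this file without code changes.
SIMVASTATIN	simvastatin
ZOCOR	simvastatin
FLOLIPID	simvastatin
SIMCOR	simvastatin
VYTORIN	simvastatin
EZETIMIBE SIMVASTATIN	simvastatin
ATORVASTATIN	atorvastatin
LIPITOR	atorvastatin
CADUET	atorvastatin
AMLODIPINE ATORVASTATIN	atorvastatin
ROSUVASTATIN	rosuvastatin
CRESTOR	rosuvastatin
EZALLOR	rosuvastatin
PRAVASTATIN	pravastatin
PRAVACHOL	pravastatin
FLUVASTATIN	fluvastatin
LESCOL	fluvastatin
LOVASTATIN	lovastatin
MEVACOR	lovastatin
ALTOPREV	lovastatin
ADVICOR	lovastatin
NIACIN LOVASTATIN	lovastatin
PITAVASTATIN	pitavastatin
LIVALO	pitavastatin
ZYPITAMAG	pitavastatin
CERIVASTATIN	cerivastatin
BAYCOL	cerivastatin
LIPOBAY	cerivastatin
COLCHICINE	colchicine
COLCRYS	colchicine
MITIGARE	colchicine
GLOPERBA	colchicine
LODOCO	colchicine
COLCHICINA	colchicine
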