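serpin_name	confirmed_targets	citation
S12c5	chymotrypsin; human chymase; cathepsin G	published inhibition assays
S13c5	trypsin IV; trypsin; FXa; FXIa; FIXa-beta; plasmin; chymase; cathepsin G	published inhibition assays
S41c10	trypsin IV; trypsin; thrombin; human chymase; alpha-chymotrypsin; cathepsin G	published inhibition assays
S45c10	porcine elastase; chymotrypsin; human chymase; cathepsin G	published inhibition assays
S48c10	kallikrein; chymotrypsin; human chymase; cathepsin G	published inhibition assays
S49c10	trypsin IV; trypsin; human chymase; cathepsin G	published inhibition assays
S51c10	trypsin; thrombin; cathepsin G; factor Xa	published inhibition assays
S61c10	trypsin IV; trypsin; factor Xa; factor XIa; plasmin; cathepsin G	published inhibition assays
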