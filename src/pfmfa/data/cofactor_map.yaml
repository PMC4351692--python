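# Substrate-level cofactor stoichiometries (mol per mol reaction flux) for
# the packaged network.  Positive = production.  ATP covers substrate-level
# phosphorylation only; oxidative phosphorylation is outside the fitted
# network.  FADH2 (succinate dehydrogenase) is not counted as NADH.
# Isocitrate dehydrogenase (icd) and malic enzyme (mae) are NADPH-dependent;
# akgd lumps the 2-oxoglutarate dehydrogenase and succinyl-CoA synthetase
# steps (one NADH, one ATP-equivalent); gapd lumps GAPDH and phosphoglycerate
# kinase; gat lumps the NAD-dependent glyceraldehyde dehydrogenase and
# glycerate 2-kinase.
upt:  {ATP: -1}
fruk: {ATP: -1}
gat:  {NADH: 1, ATP: -1}
zwf:  {NADPH: 1}
gnd:  {NADPH: 1}
gapd: {NADH: 1, ATP: 1}
pyk:  {ATP: 1}
pdh:  {NADH: 1}
icd:  {NADPH: 1}
akgd: {NADH: 1, ATP: 1}
mdh:  {NADH: 1}
mae:  {NADPH: 1}
pc:   {ATP: -1}
pck:  {ATP: -1}
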