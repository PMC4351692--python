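# Reduced atom-mapped model of P. fluorescens SBW25 central carbon metabolism
# growing on fructose.  Routes: fructose uptake via F1P (PTS entry, carbon
# only), EMP with gluconeogenic FBPase only (no phosphofructokinase), the
# Entner-Doudoroff pathway, oxidative and non-oxidative PPP, TCA cycle with
# glyoxylate shunt, anaplerosis (PEP carboxylase / PEP carboxykinase, malic
# enzyme, pyruvate carboxylase) and a fixed-composition biomass drain.
# Lumping: 1,3-bisphosphoglycerate / 3-phosphoglycerate / 2-phosphoglycerate
# as one pool PG23; glyceraldehyde -> glycerate -> 2-phosphoglycerate as one
# step (gat); citrate + isocitrate as ICIT; KDPG folded into the EDP step;
# succinyl-CoA folded into akgd.  Succinate and fumarate are symmetric
# molecules: every producing direction carries two equally weighted atom maps.
# CO2 is a balanced, labelled pool drained by co2_out.
# Biomass drain coefficients are mmol precursor per gDW, scaled so total
# biomass carbon is 35 mmolC/gDW (mu = 0.04 1/h -> 1.4 mmolC/(gDW h)).

@metabolites
FRUx  6 boundary
CO2x  1 boundary
BIOM  0 boundary
F1P   6 balanced
FBP   6 balanced
F6P   6 balanced
G6P   6 balanced
PGN6  6 balanced
RU5P  5 balanced
R5P   5 balanced
X5P   5 balanced
S7P   7 balanced
E4P   4 balanced
DHAP  3 balanced
GAP   3 balanced
GA    3 balanced
PG23  3 balanced
PEP   3 balanced
PYR   3 balanced
ACCOA 2 balanced
ICIT  6 balanced
GLX   2 balanced
AKG   5 balanced
SUC   4 balanced
FUM   4 balanced
MAL   4 balanced
OAA   4 balanced
CO2   1 balanced

@substrate
FRUx

@reactions
upt: FRUx -> F1P | FRUx#abcdef -> F1P#abcdef | irreversible | EC 2.7.1.202
fruk: F1P -> FBP | F1P#abcdef -> FBP#abcdef | irreversible | EC 2.7.1.56
f1pa: F1P -> DHAP + GA | F1P#abcdef -> DHAP#cba + GA#def | irreversible | EC 4.1.2.13
gat: GA -> PG23 | GA#abc -> PG23#abc | irreversible | EC 1.1.1.29+2.7.1.31
fba: FBP -> DHAP + GAP | FBP#abcdef -> DHAP#cba + GAP#def | reversible | EC 4.1.2.13
tpi: DHAP -> GAP | DHAP#abc -> GAP#abc | reversible | EC 5.3.1.1
fbp: FBP -> F6P | FBP#abcdef -> F6P#abcdef | irreversible | EC 3.1.3.11
pgi: F6P -> G6P | F6P#abcdef -> G6P#abcdef | reversible | EC 5.3.1.9
zwf: G6P -> PGN6 | G6P#abcdef -> PGN6#abcdef | irreversible | EC 1.1.1.49
edd: PGN6 -> PYR + GAP | PGN6#abcdef -> PYR#abc + GAP#def | irreversible | EC 4.2.1.12
gnd: PGN6 -> RU5P + CO2 | PGN6#abcdef -> RU5P#bcdef + CO2#a | irreversible | EC 1.1.1.44
rpi: RU5P -> R5P | RU5P#abcde -> R5P#abcde | reversible | EC 5.3.1.6
rpe: RU5P -> X5P | RU5P#abcde -> X5P#abcde | reversible | EC 5.1.3.1
tkt1: X5P + R5P -> S7P + GAP | X5P#abcde + R5P#fghij -> S7P#abfghij + GAP#cde | reversible | EC 2.2.1.1
tal: S7P + GAP -> E4P + F6P | S7P#abcdefg + GAP#hij -> E4P#defg + F6P#abchij | reversible | EC 2.2.1.2
tkt2: X5P + E4P -> F6P + GAP | X5P#abcde + E4P#fghi -> F6P#abfghi + GAP#cde | reversible | EC 2.2.1.1
gapd: GAP -> PG23 | GAP#abc -> PG23#abc | reversible | EC 1.2.1.12
eno: PG23 -> PEP | PG23#abc -> PEP#abc | reversible | EC 4.2.1.11
pyk: PEP -> PYR | PEP#abc -> PYR#abc | irreversible | EC 2.7.1.40
pdh: PYR -> ACCOA + CO2 | PYR#abc -> ACCOA#bc + CO2#a | irreversible | EC 1.2.4.1
cs: ACCOA + OAA -> ICIT | ACCOA#ef + OAA#abcd -> ICIT#dcbfea | irreversible | EC 2.3.3.1
icd: ICIT -> AKG + CO2 | ICIT#abcdef -> AKG#abcde + CO2#f | irreversible | EC 1.1.1.42
akgd: AKG -> SUC + CO2 | AKG#abcde -> SUC#bcde + CO2#a ; AKG#abcde -> SUC#edcb + CO2#a | irreversible | EC 1.2.4.2
sdh: SUC -> FUM | SUC#abcd -> FUM#abcd ; SUC#abcd -> FUM#dcba | reversible | EC 1.3.5.1
fum: FUM -> MAL | FUM#abcd -> MAL#abcd ; FUM#abcd -> MAL#dcba | reversible | EC 4.2.1.2
mdh: MAL -> OAA | MAL#abcd -> OAA#abcd | reversible | EC 1.1.1.37
icl: ICIT -> GLX + SUC | ICIT#abcdef -> GLX#fc + SUC#abde ; ICIT#abcdef -> GLX#fc + SUC#edba | irreversible | EC 4.1.3.1
ms: GLX + ACCOA -> MAL | GLX#ab + ACCOA#cd -> MAL#abdc | irreversible | EC 2.3.3.9
mae: MAL -> PYR + CO2 | MAL#abcd -> PYR#abc + CO2#d | irreversible | EC 1.1.1.40
pc: PYR + CO2 -> OAA | PYR#abc + CO2#d -> OAA#abcd | irreversible | EC 6.4.1.1
ppc: PEP + CO2 -> OAA | PEP#abc + CO2#d -> OAA#abcd | irreversible | EC 4.1.1.31
pck: OAA -> PEP + CO2 | OAA#abcd -> PEP#abc + CO2#d | irreversible | EC 4.1.1.49
co2_out: CO2 -> CO2x | CO2#a -> CO2x#a | irreversible |
bm: 0.205 G6P + 0.075 F6P + 0.35 R5P + 0.25 E4P + 0.125 GAP + 1.19 PG23 + 0.52 PEP + 2.55 PYR + 2.5 ACCOA + 1.52 OAA + 1.267 AKG -> BIOM | - | irreversible |
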