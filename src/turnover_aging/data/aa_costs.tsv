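# Per-residue biosynthetic cost table.
#
# energy_cost: ATP-equivalents per residue, Akashi & Gojobori (PNAS 99:3695,
#   2002). avECPA = mean energy_cost over a protein's sequence.
# decay_normalized_metric: energy cost normalized by amino acid decay rate.
#   PLACEHOLDER values: the human-calibrated per-residue metrics are not
#   reprinted here; these defaults only reproduce the qualitative classes
#   (cysteine/aspartate/asparagine metabolically expensive at > 60;
#   glycine/alanine/serine affordable at < 20).  Replace this column with
#   transcribed reference values for quantitative use; this file is the
#   single source of truth for both columns.
residue	energy_cost	decay_normalized_metric
A	11.7	18.0
R	27.3	35.0
N	14.7	70.0
D	12.7	66.0
C	24.7	86.0
E	15.3	25.0
Q	16.3	40.0
G	11.7	15.0
H	38.3	55.0
I	32.3	30.0
L	27.3	24.0
K	30.3	33.0
M	34.3	50.0
F	52.0	45.0
P	20.3	22.0
S	11.7	14.0
T	21.3	26.0
W	74.3	58.0
Y	50.0	42.0
V	23.3	21.0
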