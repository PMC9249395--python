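# "Seal" parameter set: the alternative documented baseline (narrower,
# more slowly growing tooth site).  The source text quotes seal Act/Inh
# values inconsistently in two places; as with the shark preset, these
# are this package's own calibrated values, kept as a distinct preset
# rather than reconciled.
act = 1.08
inh = 10.4
deg = 0.03
da = 0.01
di = 0.4
sec = 0.3
bwi = 15
bgr = 0.003
bia = 1.0
pro = 0.001
n_iter = 11000
seed = 0
bas = 0.00045
kap = 0.15
dega = 0.03
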