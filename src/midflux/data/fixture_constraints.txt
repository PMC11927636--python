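# Fixed exchange rates (experimentally measured uptake/secretion rates,
# arbitrary rate units). These close enough degrees of freedom that all
# branch fluxes except the citrate oxidation/efflux split are identifiable
# from the measured MIDs.
FIX v_upt 10
FIX v_serup 2
FIX v_alaup 2
FIX v_fao 1
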