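# Reaction roles used by the flux indices.
ROLE glucose_uptake = v_upt
ROLE lactate_excretion = v_ldh
ROLE pyruvate_to_tca = v_pdh
ROLE citrate_efflux_route = v_cit_exp
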