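phrase,variants
chlorine dioxide,chlorinedioxide|chloride dioxide|chorine dioxide|clorine dioxide|clorinedioxide
fortify humic beverage concentrate,fortify humic beverage concentrates|fortify humic beverage cocentrate
electrify fulvic beverage concentrate,electrify fulvic beverage cocentrate|electrify fulvic beverage concetrate|electrify fulvic beverage concentrates
supersilver whitening toothpaste,supersilver whitening toothpast|supersilver whitening toothpastes|supersilver whitening tooth paste
superblue fluoride free toothpaste,superblue fluoride free tooth paste|superblue fluoride free toothpastes|superblue fluoride free toothpast
prefense hand sanitizers,prefense handsanitzers|prefense hand sanitizes|prefense hand sanitiers|prefense hand andsanitizers|prefense hand|prefense hand handsantizers|prefense hand handsanitzers|prefense handsantizer|prefense handsanitizers|prefense|prefense hand santitizers|prefense handsanitisers|prefense handsanitzer
covid-19 cough syrup,covid 19 cough syrups|covid 19 coughsyrup|covid 19 cough syrup|covid 19 cough coughsyrup
ncov19 spike protein,ncov19 spike spike protein|ncov19 spike spikeproteins|ncov19 spike protei|ncov19 spikey proteins|ncov19 spike spikeprotein|ncov19 spikeprotien|ncov19 spike proteins|ncov19 spike spikey proteins|ncov19 spikeprotein|ncov19 spikeproteins|ncov19 spike spikeprotien
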