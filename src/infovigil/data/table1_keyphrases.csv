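phrase,type,first_letter_date,variants
antimicrobial solution,treatment,2020-11-02,
aromatherapy,treatment,2020-03-06,
ayurvedic products,treatment,2020-04-13,
bee products,treatment,2020-10-23,
berberine,treatment,2020-10-23,
betterfly,treatment,2020-09-01,
bioflavonoids,treatment,2020-10-23,
biomagnetism,treatment,2020-08-19,
chlorine dioxide,treatment,2020-04-08,chlorinedioxide|chloride dioxide|chorine dioxide|clorine dioxide|clorinedioxide
cod liver oil,treatment,2020-05-25,
colloidal silver,treatment,2020-03-06,
colostrum,treatment,2020-05-26,
corona-cure,treatment,2020-03-26,
covid-19 rapid test kit,test_kit,2020-06-10,
curativa,treatment,2020-06-25,
elderberry syrup,treatment,2020-11-10,
elderberry tincture,treatment,2020-03-06,
essential oil,treatment,2020-03-06,
eupatorium perfoliatum,treatment,2020-03-06,
grapefruit seed extract,treatment,2020-05-26,
hypochlorous acid,treatment,2020-11-02,
iodine products,treatment,2020-06-10,
kratom,treatment,2020-05-15,
magnetic therapy,treatment,2020-08-19,
methylene blue,treatment,2020-05-29,
nad+,treatment,2020-05-06,
nephron pharmaceuticals,treatment,2020-05-22,
niacin product,treatment,2020-09-01,
novabay,entity,2020-11-02,
oracare,treatment,2020-11-18,
pro breath,treatment,2020-11-18,
quercetin,treatment,2020-06-15,
salt therapy,treatment,2020-03-30,
santiste,entity,2020-04-27,
super c,treatment,2020-04-21,
superblue silver immune gargle,treatment,2020-04-09,
supersilver whitening toothpaste,treatment,2020-04-09,supersilver whitening toothpast|supersilver whitening toothpastes|supersilver whitening tooth paste
traditional chinese medicine,treatment,2020-05-08,
transdermal patch/defendtm patch,treatment,2020-04-27,
umbilical cord blood,treatment,2020-06-04,
vapore,treatment,2020-07-30,
vidacord,treatment,2020-06-04,
vivify,entity,2020-03-06,
xosomes,treatment,2020-06-04,
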