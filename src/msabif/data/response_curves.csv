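group,driver,landuse_class,c0,c1,transform,fixed_msa,covariate_units
plants,climate,,-2.87,0.467,identity,,degC
vertebrates,climate,,-3.21,0.362,identity,,degC
plants,nitrogen,,-2.19,0.743,log,,kg_ha_yr
plants,habitat_loss,cropland,1.44,0,none,,none
plants,habitat_loss,pasture,1.11,0,none,,none
plants,habitat_loss,plantation,0.920,0,none,,none
plants,habitat_loss,urban,1.10,0,none,,none
plants,habitat_loss,mine,0,0,none,0,none
vertebrates,habitat_loss,cropland,0.296,0,none,,none
vertebrates,habitat_loss,pasture,0.135,0,none,,none
vertebrates,habitat_loss,plantation,-0.212,0,none,,none
vertebrates,habitat_loss,urban,1.15,0,none,,none
vertebrates,habitat_loss,mine,0,0,none,0,none
vertebrates,fragmentation,,0.774,-0.594,log,,ha
vertebrates,disturbance,,1.77,-1.39,log,,m
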