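site_group,predator,item,kind,value
chandratal,snow_leopard,n_samples,sample_size,12
chandratal,snow_leopard,blue_sheep,item,0.0
chandratal,snow_leopard,ibex,item,3.4
chandratal,snow_leopard,marmot,item,6.9
chandratal,snow_leopard,stone_marten,item,0.0
chandratal,snow_leopard,mountain_weasel,item,0.0
chandratal,snow_leopard,lagomorph,item,6.9
chandratal,snow_leopard,rodent,item,13.8
chandratal,snow_leopard,bird,item,6.9
chandratal,snow_leopard,insect,item,0.0
chandratal,snow_leopard,goat,item,17.2
chandratal,snow_leopard,sheep,item,6.9
chandratal,snow_leopard,yak_cattle,item,20.7
chandratal,snow_leopard,horse_donkey,item,0.0
chandratal,snow_leopard,plant_material,item,13.8
chandratal,snow_leopard,plastic_paper,item,0.0
chandratal,snow_leopard,unidentified,item,3.4
chandratal,snow_leopard,wild_animals,aggregate,37.9
chandratal,snow_leopard,domestic_animals,aggregate,44.8
chandratal,snow_leopard,others,aggregate,17.2
chandratal,red_fox,n_samples,sample_size,16
chandratal,red_fox,blue_sheep,item,0.0
chandratal,red_fox,ibex,item,0.0
chandratal,red_fox,marmot,item,8.7
chandratal,red_fox,stone_marten,item,2.2
chandratal,red_fox,mountain_weasel,item,6.5
chandratal,red_fox,lagomorph,item,6.5
chandratal,red_fox,rodent,item,19.6
chandratal,red_fox,bird,item,13.0
chandratal,red_fox,insect,item,2.2
chandratal,red_fox,goat,item,4.3
chandratal,red_fox,sheep,item,4.3
chandratal,red_fox,yak_cattle,item,13.0
chandratal,red_fox,horse_donkey,item,2.2
chandratal,red_fox,plant_material,item,13.0
chandratal,red_fox,plastic_paper,item,2.2
chandratal,red_fox,unidentified,item,2.2
chandratal,red_fox,wild_animals,aggregate,58.7
chandratal,red_fox,domestic_animals,aggregate,23.9
chandratal,red_fox,others,aggregate,17.4
chandratal,wolf,n_samples,sample_size,29
chandratal,wolf,blue_sheep,item,0.0
chandratal,wolf,ibex,item,2.9
chandratal,wolf,marmot,item,0.0
chandratal,wolf,stone_marten,item,0.0
chandratal,wolf,mountain_weasel,item,0.0
chandratal,wolf,lagomorph,item,0.0
chandratal,wolf,rodent,item,8.6
chandratal,wolf,bird,item,2.9
chandratal,wolf,insect,item,0.0
chandratal,wolf,goat,item,20.0
chandratal,wolf,sheep,item,17.1
chandratal,wolf,yak_cattle,item,34.3
chandratal,wolf,horse_donkey,item,0.0
chandratal,wolf,plant_material,item,11.4
chandratal,wolf,plastic_paper,item,0.0
chandratal,wolf,unidentified,item,2.9
chandratal,wolf,wild_animals,aggregate,14.4
chandratal,wolf,domestic_animals,aggregate,71.4
chandratal,wolf,others,aggregate,14.3
kibber,snow_leopard,n_samples,sample_size,47
kibber,snow_leopard,blue_sheep,item,19.6
kibber,snow_leopard,ibex,item,7.8
kibber,snow_leopard,marmot,item,2.0
kibber,snow_leopard,stone_marten,item,0.0
kibber,snow_leopard,mountain_weasel,item,0.0
kibber,snow_leopard,lagomorph,item,5.9
kibber,snow_leopard,rodent,item,2.0
kibber,snow_leopard,bird,item,13.7
kibber,snow_leopard,insect,item,0.0
kibber,snow_leopard,goat,item,9.8
kibber,snow_leopard,sheep,item,7.8
kibber,snow_leopard,yak_cattle,item,11.8
kibber,snow_leopard,horse_donkey,item,15.7
kibber,snow_leopard,plant_material,item,3.9
kibber,snow_leopard,plastic_paper,item,0.0
kibber,snow_leopard,unidentified,item,0.0
kibber,snow_leopard,wild_animals,aggregate,51.0
kibber,snow_leopard,domestic_animals,aggregate,45.1
kibber,snow_leopard,others,aggregate,3.9
kibber,red_fox,n_samples,sample_size,134
kibber,red_fox,blue_sheep,item,4.6
kibber,red_fox,ibex,item,0.0
kibber,red_fox,marmot,item,0.0
kibber,red_fox,stone_marten,item,0.0
kibber,red_fox,mountain_weasel,item,0.0
kibber,red_fox,lagomorph,item,24.2
kibber,red_fox,rodent,item,15.0
kibber,red_fox,bird,item,2.6
kibber,red_fox,insect,item,5.9
kibber,red_fox,goat,item,9.2
kibber,red_fox,sheep,item,0.0
kibber,red_fox,yak_cattle,item,13.1
kibber,red_fox,horse_donkey,item,0.7
kibber,red_fox,plant_material,item,19.6
kibber,red_fox,plastic_paper,item,4.6
kibber,red_fox,unidentified,item,0.7
kibber,red_fox,wild_animals,aggregate,52.3
kibber,red_fox,domestic_animals,aggregate,22.9
kibber,red_fox,others,aggregate,24.9
kibber,wolf,n_samples,sample_size,50
kibber,wolf,blue_sheep,item,7.1
kibber,wolf,ibex,item,3.6
kibber,wolf,marmot,item,1.8
kibber,wolf,stone_marten,item,0.0
kibber,wolf,mountain_weasel,item,0.0
kibber,wolf,lagomorph,item,0.0
kibber,wolf,rodent,item,12.5
kibber,wolf,bird,item,1.8
kibber,wolf,insect,item,0.0
kibber,wolf,goat,item,12.5
kibber,wolf,sheep,item,8.9
kibber,wolf,yak_cattle,item,41.1
kibber,wolf,horse_donkey,item,3.6
kibber,wolf,plant_material,item,3.6
kibber,wolf,plastic_paper,item,0.0
kibber,wolf,unidentified,item,3.6
kibber,wolf,wild_animals,aggregate,26.8
kibber,wolf,domestic_animals,aggregate,66.1
kibber,wolf,others,aggregate,7.2
pin,snow_leopard,n_samples,sample_size,59
pin,snow_leopard,blue_sheep,item,0.0
pin,snow_leopard,ibex,item,41.4
pin,snow_leopard,marmot,item,0.0
pin,snow_leopard,stone_marten,item,0.0
pin,snow_leopard,mountain_weasel,item,0.0
pin,snow_leopard,lagomorph,item,2.9
pin,snow_leopard,rodent,item,0.0
pin,snow_leopard,bird,item,0.0
pin,snow_leopard,insect,item,0.0
pin,snow_leopard,goat,item,8.6
pin,snow_leopard,sheep,item,7.1
pin,snow_leopard,yak_cattle,item,11.4
pin,snow_leopard,horse_donkey,item,15.7
pin,snow_leopard,plant_material,item,11.4
pin,snow_leopard,plastic_paper,item,1.4
pin,snow_leopard,unidentified,item,0.0
pin,snow_leopard,wild_animals,aggregate,44.3
pin,snow_leopard,domestic_animals,aggregate,42.9
pin,snow_leopard,others,aggregate,12.8
pin,red_fox,n_samples,sample_size,30
pin,red_fox,blue_sheep,item,0.0
pin,red_fox,ibex,item,1.0
pin,red_fox,marmot,item,0.0
pin,red_fox,stone_marten,item,1.0
pin,red_fox,mountain_weasel,item,0.0
pin,red_fox,lagomorph,item,10.1
pin,red_fox,rodent,item,14.1
pin,red_fox,bird,item,7.1
pin,red_fox,insect,item,6.1
pin,red_fox,goat,item,4.0
pin,red_fox,sheep,item,3.0
pin,red_fox,yak_cattle,item,3.0
pin,red_fox,horse_donkey,item,1.0
pin,red_fox,plant_material,item,44.4
pin,red_fox,plastic_paper,item,0.0
pin,red_fox,unidentified,item,5.1
pin,red_fox,wild_animals,aggregate,39.4
pin,red_fox,domestic_animals,aggregate,11.1
pin,red_fox,others,aggregate,49.5
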