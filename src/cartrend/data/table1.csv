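bcr,species,method,estimate,lo,hi
Appalachian Mountains,carolina_wren,car,1.9,0.5,3.2
Appalachian Mountains,carolina_wren,nonspatial,2.2,1.0,3.45
Appalachian Mountains,cerulean_warbler,car,-2.8,-7.9,2.4
Appalachian Mountains,cerulean_warbler,nonspatial,-1.0,-3.1,1.7
Appalachian Mountains,red_bellied_woodpecker,car,3.4,2.1,4.7
Appalachian Mountains,red_bellied_woodpecker,nonspatial,3.8,2.9,4.6
Atlantic Northern Forest,carolina_wren,car,8.6,0.2,17.7
Atlantic Northern Forest,carolina_wren,nonspatial,11.6,-10.7,33.4
Atlantic Northern Forest,red_bellied_woodpecker,car,11,5.3,17
Atlantic Northern Forest,red_bellied_woodpecker,nonspatial,19.7,7.4,30.5
Boreal Hardwood Transition,cerulean_warbler,car,6.6,-12.3,29.1
Boreal Hardwood Transition,cerulean_warbler,nonspatial,-17.5,-62.0,10.7
Boreal Hardwood Transition,red_bellied_woodpecker,car,6.7,1.5,12.1
Boreal Hardwood Transition,red_bellied_woodpecker,nonspatial,9.7,3.6,15.5
Central Hardwoods,carolina_wren,car,2.1,0.7,3.5
Central Hardwoods,carolina_wren,nonspatial,2.6,1.4,3.9
Central Hardwoods,cerulean_warbler,car,3.8,-5.3,13.3
Central Hardwoods,cerulean_warbler,nonspatial,-2.1,-4.7,0.9
Central Hardwoods,red_bellied_woodpecker,car,0.1,-1.1,1.4
Central Hardwoods,red_bellied_woodpecker,nonspatial,-0.04,-1.0,0.9
Central Mixed Grass Prairie,carolina_wren,car,3.1,-1.9,8.2
Central Mixed Grass Prairie,carolina_wren,nonspatial,3.1,-2.0,8.1
Central Mixed Grass Prairie,red_bellied_woodpecker,car,1.8,-1.5,5
Central Mixed Grass Prairie,red_bellied_woodpecker,nonspatial,2.8,1.1,4.7
Eastern Tallgrass Prairie,carolina_wren,car,4.7,2.3,7.1
Eastern Tallgrass Prairie,carolina_wren,nonspatial,5.5,3.2,7.8
Eastern Tallgrass Prairie,cerulean_warbler,car,0.1,-10,11.5
Eastern Tallgrass Prairie,cerulean_warbler,nonspatial,-3.8,-15.4,13.5
Eastern Tallgrass Prairie,red_bellied_woodpecker,car,2.9,1.4,4.3
Eastern Tallgrass Prairie,red_bellied_woodpecker,nonspatial,2.0,0.9,3.1
Edwards Plateau,carolina_wren,car,1.3,-4.4,6.3
Edwards Plateau,carolina_wren,nonspatial,0.5,-3.5,4.0
Edwards Plateau,red_bellied_woodpecker,car,-2.7,-9,3.7
Edwards Plateau,red_bellied_woodpecker,nonspatial,0.3,-12.6,14.6
Gulf Coastal Prairie,carolina_wren,car,1.1,-2.7,5.1
Gulf Coastal Prairie,carolina_wren,nonspatial,5.8,3.0,9.4
Gulf Coastal Prairie,red_bellied_woodpecker,car,-1,-4.4,2.7
Gulf Coastal Prairie,red_bellied_woodpecker,nonspatial,2.3,0.1,4.5
Lower Great Lakes/St. Lawrence Plain,carolina_wren,car,2.4,-2.1,7.1
Lower Great Lakes/St. Lawrence Plain,carolina_wren,nonspatial,3.1,-2.1,8.3
Lower Great Lakes/St. Lawrence Plain,cerulean_warbler,car,-8.3,-18,3.5
Lower Great Lakes/St. Lawrence Plain,cerulean_warbler,nonspatial,-1.6,-6.4,3.0
Lower Great Lakes/St. Lawrence Plain,red_bellied_woodpecker,car,6.4,3.5,9.4
Lower Great Lakes/St. Lawrence Plain,red_bellied_woodpecker,nonspatial,6.7,5.0,8.5
Mississippi Alluvial Valley,carolina_wren,car,1.3,-0.4,2.9
Mississippi Alluvial Valley,carolina_wren,nonspatial,1.3,-0.2,2.7
Mississippi Alluvial Valley,red_bellied_woodpecker,car,-3.1,-4.8,-1.4
Mississippi Alluvial Valley,red_bellied_woodpecker,nonspatial,1.2,-0.5,2.7
New England/Mid-Atlantic Coast,carolina_wren,car,5.3,3.8,6.8
New England/Mid-Atlantic Coast,carolina_wren,nonspatial,4.7,3.2,6.4
New England/Mid-Atlantic Coast,cerulean_warbler,car,-7.9,-27.2,15.6
New England/Mid-Atlantic Coast,cerulean_warbler,nonspatial,3.6,-24.4,21.1
New England/Mid-Atlantic Coast,red_bellied_woodpecker,car,5,3,7.1
New England/Mid-Atlantic Coast,red_bellied_woodpecker,nonspatial,4.1,2.7,5.6
Oaks And Prairies,carolina_wren,car,-0.3,-2.5,1.9
Oaks And Prairies,carolina_wren,nonspatial,-0.7,-2.7,1.2
Oaks And Prairies,red_bellied_woodpecker,car,4.8,2.4,7.4
Oaks And Prairies,red_bellied_woodpecker,nonspatial,2.6,0.8,4.6
Peninsular Florida,carolina_wren,car,0.2,-1.5,1.9
Peninsular Florida,carolina_wren,nonspatial,-0.2,-1.2,0.7
Peninsular Florida,red_bellied_woodpecker,car,-0.9,-2.5,0.7
Peninsular Florida,red_bellied_woodpecker,nonspatial,-0.7,-2.0,0.6
Piedmont,carolina_wren,car,1.3,0,2.6
Piedmont,carolina_wren,nonspatial,0.8,-0.3,2.0
Piedmont,cerulean_warbler,car,-3.6,-15.3,9.5
Piedmont,cerulean_warbler,nonspatial,-0.3,-7.7,7.7
Piedmont,red_bellied_woodpecker,car,1.6,0.2,3.1
Piedmont,red_bellied_woodpecker,nonspatial,1.4,0.4,2.4
Prairie Hardwood Transition,carolina_wren,car,5.3,-2.1,13.2
Prairie Hardwood Transition,carolina_wren,nonspatial,5.1,-6.2,13.9
Prairie Hardwood Transition,cerulean_warbler,car,6.7,-6.2,21.7
Prairie Hardwood Transition,cerulean_warbler,nonspatial,-1.1,-5.4,7.3
Prairie Hardwood Transition,red_bellied_woodpecker,car,5.4,3.6,7.3
Prairie Hardwood Transition,red_bellied_woodpecker,nonspatial,4.9,3.8,6.2
Prairie Potholes,red_bellied_woodpecker,car,3.8,-2.6,10.5
Prairie Potholes,red_bellied_woodpecker,nonspatial,5.1,1.4,9.1
Southeastern Coastal Plain,carolina_wren,car,0.6,-0.4,1.6
Southeastern Coastal Plain,carolina_wren,nonspatial,0.5,-0.2,1.1
Southeastern Coastal Plain,cerulean_warbler,car,6.7,-14.8,32.1
Southeastern Coastal Plain,cerulean_warbler,nonspatial,-3.0,-53.0,105.1
Southeastern Coastal Plain,red_bellied_woodpecker,car,1.6,0.6,2.5
Southeastern Coastal Plain,red_bellied_woodpecker,nonspatial,1.0,0.5,1.5
Tamaulipan Brushlands,carolina_wren,car,-6.9,-18.1,4.4
Tamaulipan Brushlands,carolina_wren,nonspatial,6.9,1.3,14.0
West Gulf Coastal Plain/Ouachitas,carolina_wren,car,0.5,-0.8,1.8
West Gulf Coastal Plain/Ouachitas,carolina_wren,nonspatial,0.4,-0.9,1.6
West Gulf Coastal Plain/Ouachitas,cerulean_warbler,car,7.8,-26.3,56.2
West Gulf Coastal Plain/Ouachitas,cerulean_warbler,nonspatial,-15.3,-27.6,-0.4
West Gulf Coastal Plain/Ouachitas,red_bellied_woodpecker,car,1,-0.7,2.7
West Gulf Coastal Plain/Ouachitas,red_bellied_woodpecker,nonspatial,0.7,-0.3,1.6
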